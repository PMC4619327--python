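"""TCF HMG-site and Helper-site scanning of regulatory sequences.

TCF/HMG binding sites are located by text search with IUPAC consensus
strings (default: the canonical HMG consensus ``CTTTGWW``) and/or by
position-weight-matrix scoring above a threshold, on both strands.  Sites
found by more than one motif definition at the same interval are reported
once.  For each site, the flanking 20 bp up- and downstream are scanned for
GC-rich Helper motifs, which stabilise activating TCF/beta-catenin-DNA
binding.  Enrichment of site density (sites per kb) in target regulatory
regions over random draws of background regions is assessed by permutation.

Coordinates are 0-based half-open throughout; reported hit coordinates are
always on the forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "PWM",
    "MotifConfig",
    "SiteHit",
    "scan_sites",
    "site_summary",
    "enrichment_vs_background",
    "write_hits_bed",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus.upper():
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {c!r} in {consensus!r}")
        opts = IUPAC_CODES[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class PWM:
    """A position-weight matrix with a score threshold.

    ``weights`` is a (4, L) array in A, C, G, T row order (e.g. log-odds);
    a window scores as the sum of its per-position weights and matches when
    the score meets ``threshold``.
    """

    motif_id: str
    weights: tuple  # nested tuple (4, L) for hashability
    threshold: float

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def score(self, window: str) -> float:
        m = self.matrix
        if "N" in window:
            return -np.inf
        return float(sum(m[_BASE_INDEX[b], i] for i, b in enumerate(window)))


@dataclass(frozen=True)
class MotifConfig:
    """TCF and Helper motif definitions.

    The worm-specific HMG and Helper consensus strings used in the original
    site counts are not part of this package; the defaults are the widely
    used TCF/HMG consensus ``CTTTGWW`` and the Helper-family consensus
    ``GCCGCCR``, and both are plain configuration — supply your own strings
    or PWMs to reproduce any particular published count.
    """

    tcf_motifs: tuple[str, ...] = ("CTTTGWW",)
    tcf_pwms: tuple[PWM, ...] = ()
    helper_motifs: tuple[str, ...] = ("GCCGCCR",)
    helper_window: int = 20

    def __post_init__(self) -> None:
        if self.helper_window < 0:
            raise ValueError("helper_window must be >= 0")
        if not (self.tcf_motifs or self.tcf_pwms):
            raise ValueError("at least one TCF motif or PWM is required")


@dataclass(frozen=True)
class SiteHit:
    """One deduplicated TCF-site match (forward-strand coordinates)."""

    seq_id: str
    start: int
    end: int
    strand: str
    motif_id: str
    has_helper: bool = False
    score: Optional[float] = None


def _validate(seq: str) -> str:
    s = seq.upper()
    m = re.search(r"[^ACGTN]", s)
    if m:
        raise ValueError(
            f"illegal character {m.group()!r} at position {m.start()} in sequence"
        )
    return s


def _consensus_hits(seq: str, consensus: str, motif_id: str) -> list[tuple[int, int, str, str]]:
    """(start, end, strand, motif_id) for both strands, forward coordinates."""
    n = len(seq)
    out = []
    pat = _iupac_regex(consensus)
    for m in pat.finditer(seq):
        out.append((m.start(), m.start() + len(consensus), "+", motif_id))
    rc = str(Seq(seq).reverse_complement())
    for m in pat.finditer(rc):
        s = n - (m.start() + len(consensus))
        out.append((s, s + len(consensus), "-", motif_id))
    return out


def _pwm_hits(seq: str, pwm: PWM) -> list[tuple[int, int, str, str, float]]:
    n, L = len(seq), len(pwm)
    out = []
    rc = str(Seq(seq).reverse_complement())
    for i in range(n - L + 1):
        sc = pwm.score(seq[i:i + L])
        if sc >= pwm.threshold:
            out.append((i, i + L, "+", pwm.motif_id, sc))
    for i in range(n - L + 1):
        sc = pwm.score(rc[i:i + L])
        if sc >= pwm.threshold:
            s = n - (i + L)
            out.append((s, s + L, "-", pwm.motif_id, sc))
    return out


def scan_sites(seq: str, config: MotifConfig, seq_id: str = "seq") -> list[SiteHit]:
    """All TCF-site hits in a sequence, deduplicated and Helper-annotated.

    Hits from different motif definitions (or both strands of a palindromic
    motif) that cover the same interval are reported once — '+'-strand and
    consensus (text-find) matches take precedence in that order.  Each hit's
    ``has_helper`` flag is set when any Helper motif occurs within
    ``helper_window`` bp up- or downstream of the site.
    """
    s = _validate(seq)
    raw: list[tuple[int, int, str, str, Optional[float]]] = []
    for cons in config.tcf_motifs:
        raw.extend((a, b, st, mid, None) for a, b, st, mid in _consensus_hits(s, cons, cons))
    for pwm in config.tcf_pwms:
        raw.extend(_pwm_hits(s, pwm))

    # deduplicate by interval: prefer '+' strand, then consensus over PWM
    best: dict[tuple[int, int], tuple[int, int, str, str, Optional[float]]] = {}
    for hit in sorted(raw, key=lambda h: (h[0], h[1], h[2] != "+", h[4] is not None)):
        key = (hit[0], hit[1])
        if key not in best:
            best[key] = hit

    helper_ivals: list[tuple[int, int]] = []
    for helper in config.helper_motifs:
        helper_ivals.extend(
            (a, b) for a, b, _, _ in _consensus_hits(s, helper, helper)
        )

    w = config.helper_window
    out = []
    for (a, b), (_, _, strand, mid, score) in sorted(best.items()):
        has_helper = any(
            hb > a - w and ha < b + w for ha, hb in helper_ivals
        )
        out.append(SiteHit(seq_id, a, b, strand, mid, has_helper, score))
    return out


def site_summary(
    seqs: Mapping[str, str], config: MotifConfig
) -> "pd.DataFrame":
    """Per-sequence summary: TCF sites, TCF-with-Helper sites, region kb."""
    import pandas as pd

    rows = []
    for seq_id, seq in seqs.items():
        hits = scan_sites(seq, config, seq_id=seq_id)
        rows.append(
            {
                "seq_id": seq_id,
                "tcf_sites": len(hits),
                "tcf_with_helper": sum(h.has_helper for h in hits),
                "region_kb": len(seq) / 1000.0,
            }
        )
    return pd.DataFrame(rows)


def _density_per_kb(seqs: Sequence[str], config: MotifConfig) -> float:
    n_sites = sum(len(scan_sites(s, config)) for s in seqs)
    total_kb = sum(len(s) for s in seqs) / 1000.0
    if total_kb == 0:
        raise ValueError("zero total sequence length")
    return n_sites / total_kb


def enrichment_vs_background(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    config: MotifConfig,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Fold enrichment of TCF-site density in targets over background, with
    a permutation p-value.

    Each permutation draws ``len(target_seqs)`` background sequences without
    replacement and scores their site density (sites per kb); fold is the
    target density over the mean permuted density, and p is the fraction of
    permutations with density >= the target's, with +1 correction (so
    p >= 1/(n_perm + 1) always).
    """
    if not target_seqs:
        raise ValueError("no target sequences")
    if len(background_seqs) < len(target_seqs):
        raise ValueError("background must hold at least as many sequences as targets")
    rng = np.random.default_rng(seed)
    target_density = _density_per_kb(target_seqs, config)
    bg_densities = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(background_seqs), size=len(target_seqs), replace=False)
        bg_densities[i] = _density_per_kb([background_seqs[j] for j in idx], config)
    mean_bg = bg_densities.mean()
    if mean_bg == 0:
        raise ValueError("zero site density in background; fold undefined")
    fold = target_density / mean_bg
    p = (1 + int((bg_densities >= target_density).sum())) / (n_perm + 1)
    return float(fold), float(p)


def write_hits_bed(hits: Iterable[SiteHit], path) -> None:
    """BED-like 6-column output: seq, start, end, motif id, score, strand."""
    with open(path, "w") as fh:
        for h in hits:
            score = "" if h.score is None else f"{h.score:g}"
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_id}\t{score}\t{h.strand}\n")
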