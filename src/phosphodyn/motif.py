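"""Phosphorylation-motif statistics on 13-residue sequence windows.

Builds position-specific scoring matrices (PSSMs) from substrate
windows, scores candidate windows by summed log2 odds, and computes
iceLogo-style percent-difference enrichment of residues at each flank
position between a foreground and a background window set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
WINDOW_WIDTH = 13
CENTER = WINDOW_WIDTH // 2
PAD = "_"

#: flank offsets relative to the phosphosite, -6..+6
OFFSETS = list(range(-6, 7))


def aa_frequencies(windows) -> np.ndarray:
    """Overall amino-acid frequencies across all non-pad window positions."""
    counts = np.zeros(len(AMINO_ACIDS))
    for w in windows:
        for ch in w:
            if ch == PAD:
                continue
            try:
                counts[_AA_INDEX[ch]] += 1
            except KeyError:
                raise ValueError(f"unknown residue {ch!r} in window {w!r}") from None
    total = counts.sum()
    if total == 0:
        raise ValueError("no residues to count")
    return counts / total


@dataclass
class PSSM:
    """13 x 20 log2-odds matrix over a background model.

    ``freqs`` holds the pseudocount-regularized per-position foreground
    frequencies (rows sum to 1); ``log_odds`` is log2(freqs/background).
    """

    log_odds: np.ndarray
    freqs: np.ndarray
    background_freqs: np.ndarray
    pseudocount: float = 0.5
    source_count: int = 0
    offsets: list[int] = field(default_factory=lambda: list(OFFSETS))


def build_pssm(
    windows,
    background_freqs: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> PSSM:
    """PSSM from substrate windows with additive pseudocounts.

    Pad characters ('_', windows near a protein terminus) are excluded
    from the counts.  ``background_freqs`` defaults to uniform; in the
    pipeline it is the residue composition of the full site table.
    """
    windows = list(windows)
    if len(windows) < 5:
        raise ValueError("build_pssm requires at least 5 windows")
    widths = {len(w) for w in windows}
    if widths != {WINDOW_WIDTH}:
        raise ValueError(f"all windows must have width {WINDOW_WIDTH}, got {widths}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = (
        np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        if background_freqs is None
        else np.asarray(background_freqs, dtype=float)
    )
    counts = np.zeros((WINDOW_WIDTH, len(AMINO_ACIDS)))
    for w in windows:
        for pos, ch in enumerate(w):
            if ch == PAD:
                continue
            try:
                counts[pos, _AA_INDEX[ch]] += 1
            except KeyError:
                raise ValueError(f"unknown residue {ch!r} in window {w!r}") from None
    totals = counts.sum(axis=1, keepdims=True) + pseudocount * len(AMINO_ACIDS)
    freqs = (counts + pseudocount) / totals
    log_odds = np.log2(freqs / bg)
    return PSSM(
        log_odds=log_odds,
        freqs=freqs,
        background_freqs=bg,
        pseudocount=pseudocount,
        source_count=len(windows),
    )


def score_window(pssm: PSSM, window: str) -> float:
    """Summed flank log2 odds; higher = more motif-like.

    The center position is skipped (it is conditioned on being S/T/Y)
    and pad positions contribute 0.
    """
    if len(window) != WINDOW_WIDTH:
        raise ValueError(f"window must have width {WINDOW_WIDTH}")
    score = 0.0
    for pos, ch in enumerate(window):
        if pos == CENTER or ch == PAD:
            continue
        if ch not in _AA_INDEX:
            raise ValueError(f"unknown residue {ch!r} in window {window!r}")
        score += pssm.log_odds[pos, _AA_INDEX[ch]]
    return float(score)


def score_windows(pssm: PSSM, windows) -> np.ndarray:
    """Vectorized :func:`score_window` over many windows."""
    return np.array([score_window(pssm, w) for w in windows])


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with pooled variance.

    Degenerate cells (pooled proportion 0 or 1, zero variance) return
    p = 1: no evidence of a difference is obtainable.
    """
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def percent_difference_enrichment(
    foreground, background, alpha: float = 0.01
) -> pd.DataFrame:
    """iceLogo-style per-(position, residue) enrichment table.

    Scores each cell by the percent difference 100*(p_fg - p_bg) of
    residue frequencies at that flank position and flags significance by
    a two-sided two-proportion z-test at ``alpha``.  Pad characters are
    excluded from the position totals.
    """
    fg = list(foreground)
    bg = list(background)
    if not fg or not bg:
        raise ValueError("foreground and background must both be non-empty")

    def counts(windows):
        c = np.zeros((WINDOW_WIDTH, len(AMINO_ACIDS)))
        tot = np.zeros(WINDOW_WIDTH)
        for w in windows:
            if len(w) != WINDOW_WIDTH:
                raise ValueError(f"window {w!r} does not have width {WINDOW_WIDTH}")
            for pos, ch in enumerate(w):
                if ch == PAD:
                    continue
                c[pos, _AA_INDEX[ch]] += 1
                tot[pos] += 1
        return c, tot

    c_fg, t_fg = counts(fg)
    c_bg, t_bg = counts(bg)
    rows = []
    for pos in range(WINDOW_WIDTH):
        if t_fg[pos] == 0 or t_bg[pos] == 0:
            continue
        for ai, aa in enumerate(AMINO_ACIDS):
            p_fg = c_fg[pos, ai] / t_fg[pos]
            p_bg = c_bg[pos, ai] / t_bg[pos]
            pval = _two_proportion_p(
                int(c_fg[pos, ai]), int(t_fg[pos]), int(c_bg[pos, ai]), int(t_bg[pos])
            )
            rows.append(
                {
                    "position": OFFSETS[pos],
                    "residue": aa,
                    "freq_foreground": p_fg,
                    "freq_background": p_bg,
                    "percent_difference": 100.0 * (p_fg - p_bg),
                    "pvalue": pval,
                    "significant": pval < alpha,
                }
            )
    return pd.DataFrame(rows)
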