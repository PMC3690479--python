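"""Abundance ranking and enrichment statistics.

iBAQ-style protein abundance (summed peptide intensity divided by the
number of theoretically observable tryptic peptides) with quartile
ranking; Fisher's-exact term enrichment against a background set with
Benjamini-Hochberg FDR control; and a Wilcoxon rank-sum comparison of
phosphoprotein abundance ranks against the remaining proteome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def count_tryptic_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of fully tryptic peptides with length in [min_len, max_len].

    Cleavage C-terminal to K or R except when followed by P; no missed
    cleavages.  This is the iBAQ denominator convention.
    """
    if not sequence:
        return 0
    fragments = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    return sum(1 for f in fragments if min_len <= len(f) <= max_len)


def rank_quartiles(records: pd.DataFrame) -> pd.DataFrame:
    """iBAQ values, descending abundance ranks and quartile labels.

    Input columns: protein_id, summed_intensity, theoretical_peptides.
    Rank 1 is the most abundant protein; ties are broken
    deterministically by protein id; quartile boundaries fall at n/4
    counts (Q1 = most abundant quarter).
    """
    required = {"protein_id", "summed_intensity", "theoretical_peptides"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if len(records) < 4:
        raise ValueError("rank_quartiles requires at least 4 proteins")
    if (records["theoretical_peptides"] < 1).any():
        raise ValueError("theoretical_peptides must be >= 1")
    df = records.copy()
    df["ibaq"] = df["summed_intensity"] / df["theoretical_peptides"]
    df = df.sort_values(
        ["ibaq", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["quartile"] = ["Q" + str(int((r - 1) * 4 // n) + 1) for r in df["rank"]]
    return df


def fisher_enrichment(
    term_members: set, foreground: set, background: set
) -> tuple[float, float]:
    """Fisher's exact test of term membership in a foreground set.

    2x2 table of (in/out of term) x (in/out of foreground) over the
    background universe; returns (odds ratio, two-sided exact p).  An
    infinite odds ratio (empty off-diagonal cell) is reported as inf.
    """
    foreground = set(foreground)
    background = set(background)
    term = set(term_members) & background
    if not foreground:
        raise ValueError("foreground must be non-empty")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    rest = background - foreground
    a = len(term & foreground)
    b = len(foreground) - a
    c = len(term & rest)
    d = len(rest) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_fdr(pvals, alpha: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p values, significant flags at ``alpha``).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p values must lie in [0, 1]")
    flags, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, flags


def enrichment_table(
    terms: dict[str, set],
    foreground: set,
    background: set,
    fdr: float = 0.02,
) -> pd.DataFrame:
    """Fisher enrichment of many terms with BH control.

    ``terms`` maps term id -> member protein ids.  Rows are sorted by
    adjusted p value.
    """
    rows = []
    for term_id, members in terms.items():
        odds, p = fisher_enrichment(members, foreground, background)
        rows.append(
            {
                "term_id": term_id,
                "n_term": len(set(members) & set(background)),
                "n_overlap": len(set(members) & set(foreground)),
                "odds_ratio": odds,
                "pvalue": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"], df["significant"] = bh_fdr(df["pvalue"].to_numpy(), fdr)
        df = df.sort_values("p_adjusted", kind="mergesort").reset_index(drop=True)
    return df


def rank_shift_test(
    phospho_ids, all_ids, abundance_ranks: dict
) -> tuple[float, float]:
    """Wilcoxon rank-sum test for an abundance shift of phosphoproteins.

    Compares the abundance ranks of proteins in ``phospho_ids`` against
    the remaining proteins of ``all_ids``.  Small tie-free groups are
    evaluated exactly; otherwise the normal approximation with tie
    correction is used.  Returns (statistic U, two-sided p).
    """
    phospho = set(phospho_ids)
    rest = set(all_ids) - phospho
    if not phospho or not rest:
        raise ValueError("both groups must be non-empty")
    x = np.array([abundance_ranks[i] for i in sorted(phospho)], dtype=float)
    y = np.array([abundance_ranks[i] for i in sorted(rest)], dtype=float)
    no_ties = len(np.unique(np.r_[x, y])) == len(x) + len(y)
    method = "exact" if no_ties and max(len(x), len(y)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
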