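"""Insulin-regulation calling and inhibitor-dependence classification.

Sites are called insulin-regulated when their median log2(insulin/basal)
ratio exceeds a global threshold of 2.5 median absolute deviations (raw
MAD, no normal-consistency constant) of the log2-transformed data.
Pathway dependence follows a reversal rule: a site is PI3K/mTOR-dependent
if the PI3K/mTOR inhibitor (LY294002) reverses its insulin response by
more than 40%, and Akt-dependent if additionally the Akt inhibitor
(MK2206) does.  Classification is restricted to class I sites quantified
in at least one replicate of every screen arm with a consistent response
direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phosphodyn.io_tables import PhosphoSiteRecord

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"
NOT_QUANTIFIED = "not_quantified"

_CLASS_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class RegulationConfig:
    """Parameters of the regulation/dependence calling procedure.

    ``threshold_on`` selects the data the global MAD is computed from:
    "replicates" pools every replicate-level insulin log2 ratio (the
    log2-transformed measurements), "medians" uses per-site replicate
    medians.  ``mad_consistency`` rescales the raw MAD (1.4826 recovers
    the normal-consistent estimator; default raw).  ``reversal_scale``
    chooses whether reversal fractions are computed on log2 ratios
    (default) or back-transformed linear fold changes.
    """

    mad_multiplier: float = 2.5
    reversal_threshold: float = 0.40
    min_localization_class: str = "I"
    require_same_direction_both_screens: bool = True
    threshold_on: str = "replicates"
    mad_consistency: float = 1.0
    reversal_scale: str = "log2"

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be > 0")
        if not 0.0 < self.reversal_threshold < 1.0:
            raise ValueError("reversal_threshold must lie in (0, 1)")
        if self.min_localization_class not in _CLASS_ORDER:
            raise ValueError("min_localization_class must be I, II, III or IV")
        if self.threshold_on not in ("replicates", "medians"):
            raise ValueError("threshold_on must be 'replicates' or 'medians'")
        if self.reversal_scale not in ("log2", "linear"):
            raise ValueError("reversal_scale must be 'log2' or 'linear'")

    @classmethod
    def from_dict(cls, d: dict) -> "RegulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown regulation config key(s): {sorted(unknown)}")
        return cls(**d)


def localization_class(prob: float) -> str:
    """Localization class from the site localization probability.

    class I: prob > 0.75; class II: 0.5 < prob <= 0.75;
    class III: 0.25 < prob <= 0.5; class IV: prob <= 0.25.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"localization probability must lie in [0,1], got {prob}")
    if prob > 0.75:
        return "I"
    if prob > 0.5:
        return "II"
    if prob > 0.25:
        return "III"
    return "IV"


def mad(values) -> float:
    """Raw median absolute deviation, median(|x - median(x)|)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("mad requires at least one finite value")
    return float(np.median(np.abs(x - np.median(x))))


def mad_threshold(values, multiplier: float = 2.5, consistency: float = 1.0) -> float:
    """Regulation threshold: multiplier x (raw MAD) of the log2 ratios."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("mad_threshold requires at least 3 finite values")
    m = mad(x) * consistency
    if m == 0.0:
        warnings.warn(
            "degenerate input: all values identical, MAD threshold is 0",
            stacklevel=2,
        )
    return multiplier * m


def call_direction(median_log2: float, threshold: float) -> str:
    """up / down / none by strict comparison against +-threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not np.isfinite(median_log2):
        return NOT_QUANTIFIED
    if median_log2 > threshold:
        return DIRECTION_UP
    if median_log2 < -threshold:
        return DIRECTION_DOWN
    return DIRECTION_NONE


def call_regulation(record: PhosphoSiteRecord, threshold: float) -> str:
    """Insulin-response direction of one site at a given global threshold."""
    if record.inhibitor_quant is None or not record.inhibitor_quant.arm_quantified("ins"):
        return NOT_QUANTIFIED
    return call_direction(record.inhibitor_quant.ins_median, threshold)


def reversal_fraction(insulin_log2: float, inhibitor_log2: float) -> float:
    """Fraction of the insulin response abolished in the inhibitor arm.

    1 - inhibitor/insulin on the log2 scale; 1 = full reversal, 0 = no
    effect, negative = potentiation.  Sign-symmetric for down-regulated
    sites (both ratios negative).  Undefined for insulin_log2 == 0.
    """
    if insulin_log2 == 0:
        raise ValueError("reversal fraction undefined for zero insulin response")
    return 1.0 - inhibitor_log2 / insulin_log2


def _reversal_linear(insulin_log2: float, inhibitor_log2: float) -> float:
    num = 2.0**inhibitor_log2 - 1.0
    den = 2.0**insulin_log2 - 1.0
    return 1.0 - num / den


def compute_threshold(records, config: RegulationConfig | None = None) -> float:
    """Global 2.5-MAD threshold from the insulin-arm log2 ratios.

    One threshold is computed from the full distribution (regulated and
    unregulated sites together).
    """
    config = config or RegulationConfig()
    vals: list[float] = []
    for r in records:
        if r.inhibitor_quant is None:
            continue
        if config.threshold_on == "replicates":
            arm = r.inhibitor_quant.ins_log2
            vals.extend(arm[np.isfinite(arm)].tolist())
        else:
            m = r.inhibitor_quant.ins_median
            if np.isfinite(m):
                vals.append(m)
    return mad_threshold(vals, config.mad_multiplier, config.mad_consistency)


def call_regulation_table(
    records, config: RegulationConfig | None = None, threshold: float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Direction + dependence calls for a cohort of sites.

    Returns the per-site call table and a summary with the threshold,
    counts, and the two headline dependence fractions.  The filters
    (localization class, quantification in every screen arm, consistent
    direction) gate only the dependence classification; directions are
    reported for every quantified site.
    """
    config = config or RegulationConfig()
    records = list(records)
    if threshold is None:
        threshold = compute_threshold(records, config)

    max_class = _CLASS_ORDER[config.min_localization_class]
    rows = []
    for r in records:
        q = r.inhibitor_quant
        ins_med = q.ins_median if q is not None else math.nan
        mk_med = q.mk_median if q is not None else math.nan
        ly_med = q.ly_median if q is not None else math.nan
        quantified = q is not None and q.arm_quantified("ins")
        direction = (
            call_direction(ins_med, threshold) if quantified else NOT_QUANTIFIED
        )
        loc_class = localization_class(r.localization_prob)
        all_arms = q is not None and all(
            q.arm_quantified(a) for a in ("ins", "mk", "ly")
        )
        passed = (
            _CLASS_ORDER[loc_class] <= max_class
            and all_arms
            and (
                direction in (DIRECTION_UP, DIRECTION_DOWN)
                or not config.require_same_direction_both_screens
            )
        )
        rows.append(
            {
                "site_id": r.site_id,
                "localization_class": loc_class,
                "insulin_log2_median": ins_med,
                "mk_log2_median": mk_med,
                "ly_log2_median": ly_med,
                "direction": direction,
                "passed_filters": passed,
            }
        )
    calls = pd.DataFrame(rows)
    calls, summary = classify_dependence(calls, config)
    n_quant = int((calls["direction"] != NOT_QUANTIFIED).sum())
    n_reg = int(calls["direction"].isin([DIRECTION_UP, DIRECTION_DOWN]).sum())
    summary.update(
        {
            "threshold": float(threshold),
            "n_sites": len(calls),
            "n_quantified": n_quant,
            "n_up": int((calls["direction"] == DIRECTION_UP).sum()),
            "n_down": int((calls["direction"] == DIRECTION_DOWN).sum()),
            "n_regulated": n_reg,
            "frac_regulated": n_reg / n_quant if n_quant else math.nan,
        }
    )
    return calls, summary


def classify_dependence(
    calls: pd.DataFrame, config: RegulationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Annotate PI3K/mTOR- and Akt-dependence on a call table.

    A site is PI3K-dependent if the LY arm reverses its insulin response
    by more than the threshold, and Akt-dependent if additionally the MK
    arm does.  Only sites passing the upstream filters and carrying a
    definite direction contribute to the summary fractions: (a) fraction
    of regulated sites that are PI3K-dependent and (b) fraction of
    PI3K-dependent sites that are also Akt-dependent.
    """
    config = config or RegulationConfig()
    if len(calls) == 0:
        raise ValueError("empty call table")
    calls = calls.copy()
    rev = reversal_fraction if config.reversal_scale == "log2" else _reversal_linear

    rev_ly = np.full(len(calls), np.nan)
    rev_mk = np.full(len(calls), np.nan)
    pi3k = np.zeros(len(calls), dtype=bool)
    akt = np.zeros(len(calls), dtype=bool)
    eligible = np.zeros(len(calls), dtype=bool)
    for i, row in enumerate(calls.itertuples(index=False)):
        if not (
            row.passed_filters
            and row.direction in (DIRECTION_UP, DIRECTION_DOWN)
            and np.isfinite(row.insulin_log2_median)
            and row.insulin_log2_median != 0.0
        ):
            continue
        eligible[i] = True
        if np.isfinite(row.ly_log2_median):
            rev_ly[i] = rev(row.insulin_log2_median, row.ly_log2_median)
        if np.isfinite(row.mk_log2_median):
            rev_mk[i] = rev(row.insulin_log2_median, row.mk_log2_median)
        pi3k[i] = np.isfinite(rev_ly[i]) and rev_ly[i] > config.reversal_threshold
        akt[i] = (
            pi3k[i]
            and np.isfinite(rev_mk[i])
            and rev_mk[i] > config.reversal_threshold
        )
    calls["reversal_ly"] = rev_ly
    calls["reversal_mk"] = rev_mk
    calls["pi3k_dependent"] = pi3k
    calls["akt_dependent"] = akt

    n_eligible = int(eligible.sum())
    n_pi3k = int(pi3k.sum())
    n_akt = int(akt.sum())
    summary = {
        "n_regulated_filtered": n_eligible,
        "n_pi3k_dependent": n_pi3k,
        "n_akt_dependent": n_akt,
        "frac_pi3k_dependent": n_pi3k / n_eligible if n_eligible else math.nan,
        "frac_akt_among_pi3k": n_akt / n_pi3k if n_pi3k else 0.0,
    }
    if n_eligible == 0:
        warnings.warn(
            "no regulated sites pass the dependence filters; "
            "summary fractions are undefined",
            stacklevel=2,
        )
    return calls, summary


def residue_distribution(records) -> dict[str, float]:
    """Fractions of phospho-S/T/Y among the given records (sum to 1)."""
    records = list(records)
    if not records:
        raise ValueError("residue_distribution requires a non-empty input")
    counts = {"S": 0, "T": 0, "Y": 0}
    for r in records:
        counts[r.residue] += 1
    n = len(records)
    return {aa: c / n for aa, c in counts.items()}
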