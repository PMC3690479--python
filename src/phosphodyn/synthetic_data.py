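"""Synthetic phosphoproteome screens with planted ground truth.

The generator emulates the study design of two SILAC screens in
insulin-stimulated adipocytes: a 9-point insulin time course (0, 15 s,
30 s, 1, 2, 5, 10, 20, 60 min) and a two-inhibitor screen (insulin,
insulin + Akt inhibitor MK2206, insulin + PI3K/mTOR inhibitor LY294002,
each vs basal).  Every site carries planted labels — regulation,
direction, temporal archetype, pathway dependence, generating kinase —
so downstream stages can be scored against known truth.

Defaults mirror the printed composition of the real dataset:
~15% insulin-regulated sites with a ~2:1 up:down split, 87.8/11.4/0.8
S/T/Y residue frequencies, 63% class I localization, >50% of the
regulated response PI3K-blocked and ~67% of that Akt-blocked.  Temporal
archetypes are kinase-like: Akt substrates reach plateau within 1 min,
mTORC1 substrates ramp slowly, transient sites peak at 1–2 min and
decay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phosphodyn.io_tables import (
    InhibitorScreenRecord,
    PhosphoSiteRecord,
)
from phosphodyn.temporal import TIMEPOINTS_MIN, TimeCourseProfile

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ARCH_FAST = "fast_sustained"
ARCH_SLOW = "slow_ramp"
ARCH_TRANSIENT = "transient"
ARCH_DECREASED = "decreased"
ARCH_FLAT = "flat"

KINASES = ("Akt", "mTORC1", "PKA")

#: Flank-position preferences of the generator's kinase motif models
#: (offset relative to the phosphosite -> {residue: probability}).
#: Akt-like basophilic R-x-R-x-x-S/T; PKA-like R-R-x-S/T; mTORC1-like
#: proline-directed at +1.  Remaining probability mass is uniform over
#: the other letters.
KINASE_MOTIFS: dict[str, dict[int, dict[str, float]]] = {
    "Akt": {-5: {"R": 0.70}, -3: {"R": 0.80}},
    "PKA": {-3: {"R": 0.80}, -2: {"R": 0.80}},
    "mTORC1": {1: {"P": 0.80}},
}

# time constants (minutes) of the noiseless template curves
_TAU_FAST = 0.25  # >=95% of plateau by 1 min
_TAU_SLOW = 7.0  # plateau reached between 10 and 60 min
_TAU_TRANS_RISE = 0.3
_TAU_TRANS_DECAY = 8.0


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic screens."""

    n_sites: int = 20_000
    frac_regulated: float = 0.15
    frac_up_among_regulated: float = 0.667
    frac_pi3k_dependent_among_regulated: float = 0.55
    frac_akt_dependent_among_pi3k: float = 0.67
    residue_freqs: dict[str, float] = field(
        default_factory=lambda: {"S": 0.878, "T": 0.114, "Y": 0.008}
    )
    frac_class1: float = 0.63
    archetype_mix_among_up: dict[str, float] = field(
        default_factory=lambda: {
            ARCH_FAST: 0.5,
            ARCH_TRANSIENT: 0.3,
            ARCH_SLOW: 0.2,
        }
    )
    replicate_noise_sd: float = 0.25
    missing_rate: float = 0.10
    n_replicates: int = 3
    effect_size_mean: float = 1.5
    effect_size_sd: float = 0.5
    effect_size_min: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_regulated": self.frac_regulated,
            "frac_up_among_regulated": self.frac_up_among_regulated,
            "frac_pi3k_dependent_among_regulated": (
                self.frac_pi3k_dependent_among_regulated
            ),
            "frac_akt_dependent_among_pi3k": self.frac_akt_dependent_among_pi3k,
            "frac_class1": self.frac_class1,
            "missing_rate": self.missing_rate,
        }
        for name, v in fracs.items():
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0,1], got {v}")
        for name in ("replicate_noise_sd", "effect_size_mean", "effect_size_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if abs(sum(self.residue_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("residue_freqs must sum to 1")
        if abs(sum(self.archetype_mix_among_up.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix_among_up must sum to 1")
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("n_sites and n_replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown generator config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def template_curve(archetype: str, timepoints_min: np.ndarray | None = None) -> np.ndarray:
    """Noiseless unit-amplitude log2 template for one temporal archetype.

    Pure function of (archetype, time axis); multiply by a signed effect
    size to obtain the planted mean log2 ratio.  ``decreased`` shares
    the fast-sustained shape (the sign comes from the effect size), and
    ``flat`` is identically zero.
    """
    t = TIMEPOINTS_MIN if timepoints_min is None else np.asarray(timepoints_min)
    if archetype in (ARCH_FAST, ARCH_DECREASED):
        return 1.0 - np.exp(-t / _TAU_FAST)
    if archetype == ARCH_SLOW:
        return 1.0 - np.exp(-t / _TAU_SLOW)
    if archetype == ARCH_TRANSIENT:
        raw = np.exp(-t / _TAU_TRANS_DECAY) - np.exp(-t / _TAU_TRANS_RISE)
        fine = np.linspace(0.0, 60.0, 6001)
        peak = (np.exp(-fine / _TAU_TRANS_DECAY) - np.exp(-fine / _TAU_TRANS_RISE)).max()
        return raw / peak
    if archetype == ARCH_FLAT:
        return np.zeros_like(t, dtype=float)
    raise ValueError(f"unknown archetype {archetype!r}")


def sample_window(
    model: dict[int, dict[str, float]] | None,
    residue: str,
    rng: np.random.Generator,
    residue_freqs: dict[str, float] | None = None,
) -> str:
    """Draw one 13-mer window with the phosphosite residue at the center.

    ``model`` maps flank offsets (-6..6, 0 excluded) to preferred-letter
    probabilities; ``None`` gives the background model (uniform flanks).
    """
    if residue not in "STY":
        raise ValueError(f"center residue must be S, T or Y, got {residue!r}")
    letters = []
    for off in range(-6, 7):
        if off == 0:
            letters.append(residue)
            continue
        prefs = (model or {}).get(off)
        if prefs:
            p = np.full(len(AMINO_ACIDS), 0.0)
            rest = 1.0 - sum(prefs.values())
            others = [a for a in AMINO_ACIDS if a not in prefs]
            for a, pa in prefs.items():
                p[AMINO_ACIDS.index(a)] = pa
            for a in others:
                p[AMINO_ACIDS.index(a)] = rest / len(others)
            letters.append(AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=p)])
        else:
            letters.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
    return "".join(letters)


def _sample_windows_batch(
    model: dict[int, dict[str, float]] | None,
    residues: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized window sampling for many sites sharing one motif model."""
    n = len(residues)
    cols = []
    for off in range(-6, 7):
        if off == 0:
            cols.append(residues.astype("<U1"))
            continue
        prefs = (model or {}).get(off)
        if prefs:
            p = np.zeros(len(AMINO_ACIDS))
            rest = 1.0 - sum(prefs.values())
            n_others = len(AMINO_ACIDS) - len(prefs)
            p[:] = rest / n_others
            for a, pa in prefs.items():
                p[AMINO_ACIDS.index(a)] = pa
            idx = rng.choice(len(AMINO_ACIDS), size=n, p=p)
        else:
            idx = rng.integers(len(AMINO_ACIDS), size=n)
        cols.append(np.array(list(AMINO_ACIDS))[idx])
    mat = np.stack(cols, axis=1)
    return np.array(["".join(row) for row in mat])


def expected_kinase_fractions(config: GeneratorConfig) -> dict[str, float]:
    """Expected P(true_kinase = K | regulated) implied by the config.

    Kinase labels require compatible planted dependence and archetype:
    Akt = Akt-dependent & fast_sustained; mTORC1 = PI3K-only &
    slow_ramp; PKA = PI3K-independent & fast_sustained.
    """
    up = config.frac_up_among_regulated
    mix = config.archetype_mix_among_up
    pi3k = config.frac_pi3k_dependent_among_regulated
    akt = config.frac_akt_dependent_among_pi3k
    return {
        "Akt": up * mix.get(ARCH_FAST, 0.0) * pi3k * akt,
        "mTORC1": up * mix.get(ARCH_SLOW, 0.0) * pi3k * (1.0 - akt),
        "PKA": up * mix.get(ARCH_FAST, 0.0) * (1.0 - pi3k),
    }


def generate(config: GeneratorConfig) -> tuple[list[PhosphoSiteRecord], pd.DataFrame]:
    """Generate one synthetic cohort and its ground-truth table.

    Deterministic for a fixed ``config.seed``.  Returns the site records
    (with both screens quantified, subject to completely-at-random
    per-replicate missingness) and a DataFrame of planted labels indexed
    like the records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    n_rep = config.n_replicates

    residues = rng.choice(
        list(config.residue_freqs), size=n, p=list(config.residue_freqs.values())
    ).astype("<U1")

    regulated = rng.random(n) < config.frac_regulated
    up = regulated & (rng.random(n) < config.frac_up_among_regulated)
    down = regulated & ~up
    direction = np.where(up, "up", np.where(down, "down", "none"))

    archetype = np.full(n, ARCH_FLAT, dtype="<U14")
    mix_names = list(config.archetype_mix_among_up)
    mix_p = np.array(list(config.archetype_mix_among_up.values()))
    archetype[up] = rng.choice(mix_names, size=int(up.sum()), p=mix_p)
    archetype[down] = ARCH_DECREASED

    pi3k_dep = regulated & (
        rng.random(n) < config.frac_pi3k_dependent_among_regulated
    )
    akt_dep = pi3k_dep & (rng.random(n) < config.frac_akt_dependent_among_pi3k)

    kinase = np.full(n, "none", dtype="<U8")
    kinase[akt_dep & (archetype == ARCH_FAST)] = "Akt"
    kinase[pi3k_dep & ~akt_dep & (archetype == ARCH_SLOW)] = "mTORC1"
    kinase[regulated & ~pi3k_dep & (archetype == ARCH_FAST)] = "PKA"

    # effect sizes: truncated normal, |log2 effect| >= effect_size_min
    a = (config.effect_size_min - config.effect_size_mean) / config.effect_size_sd
    effect = stats.truncnorm.rvs(
        a, np.inf, loc=config.effect_size_mean, scale=config.effect_size_sd,
        size=n, random_state=rng,
    )
    signed_effect = np.where(regulated, np.where(up, effect, -effect), 0.0)

    # localization probability: class I drawn high in (0.75, 1], the rest
    # uniform below 0.75 (overall median near the study's 0.96)
    class1 = rng.random(n) < config.frac_class1
    loc_prob = np.where(
        class1,
        0.75 + 0.25 * rng.beta(5.0, 1.0, size=n),
        0.75 * rng.random(n),
    )

    multiplicity = rng.choice(
        [1, 2, 3, 4], size=n, p=[0.72, 0.23, 0.04, 0.01]
    )

    # ---- inhibitor screen -------------------------------------------------
    # planted reversal fractions: dependent arms reverse 60-100% of the
    # insulin response, independent arms drift in [-10%, +20%]
    rev_ly = np.where(
        pi3k_dep, rng.uniform(0.6, 1.0, n), rng.uniform(-0.1, 0.2, n)
    )
    rev_mk = np.where(
        akt_dep, rng.uniform(0.6, 1.0, n), rng.uniform(-0.1, 0.2, n)
    )
    ins_true = signed_effect
    mk_true = np.where(regulated, ins_true * (1.0 - rev_mk), 0.0)
    ly_true = np.where(regulated, ins_true * (1.0 - rev_ly), 0.0)

    def replicate(true: np.ndarray) -> np.ndarray:
        vals = true[:, None] + rng.normal(
            0.0, config.replicate_noise_sd, size=(n, n_rep)
        )
        miss = rng.random((n, n_rep)) < config.missing_rate
        vals[miss] = np.nan
        return vals

    ins_rep = replicate(ins_true)
    mk_rep = replicate(mk_true)
    ly_rep = replicate(ly_true)

    # ---- time course ------------------------------------------------------
    templates = {
        arch: template_curve(arch)
        for arch in (ARCH_FAST, ARCH_SLOW, ARCH_TRANSIENT, ARCH_DECREASED, ARCH_FLAT)
    }
    tc_true = np.zeros((n, len(TIMEPOINTS_MIN)))
    for arch, tpl in templates.items():
        mask = archetype == arch
        if mask.any():
            tc_true[mask] = signed_effect[mask, None] * tpl[None, :]
    tc_rep = tc_true[:, :, None] + rng.normal(
        0.0, config.replicate_noise_sd, size=(n, len(TIMEPOINTS_MIN), n_rep)
    )
    tc_miss = rng.random(tc_rep.shape) < config.missing_rate
    tc_rep[tc_miss] = np.nan

    # ---- sequence windows -------------------------------------------------
    windows = np.empty(n, dtype="<U13")
    window_source = np.full(n, "background", dtype="<U12")
    for kin in KINASES:
        mask = kinase == kin
        if mask.any():
            windows[mask] = _sample_windows_batch(
                KINASE_MOTIFS[kin], residues[mask], rng
            )
            window_source[mask] = kin
    bg_mask = kinase == "none"
    if bg_mask.any():
        windows[bg_mask] = _sample_windows_batch(None, residues[bg_mask], rng)

    # ---- protein bookkeeping ---------------------------------------------
    n_proteins = max(1, round(n / 6.5))
    protein_idx = rng.integers(n_proteins, size=n)
    positions = rng.integers(1, 2001, size=n)

    records: list[PhosphoSiteRecord] = []
    for i in range(n):
        records.append(
            PhosphoSiteRecord(
                site_id=f"S{i + 1:06d}",
                protein_id=f"PROT{protein_idx[i] + 1:05d}",
                gene_name=f"Gene{protein_idx[i] + 1}",
                position=int(positions[i]),
                residue=str(residues[i]),
                localization_prob=float(loc_prob[i]),
                multiplicity=int(multiplicity[i]),
                sequence_window=str(windows[i]),
                inhibitor_quant=InhibitorScreenRecord(
                    ins_log2=ins_rep[i], mk_log2=mk_rep[i], ly_log2=ly_rep[i]
                ),
                timecourse_quant=TimeCourseProfile(replicate_log2=tc_rep[i]),
            )
        )

    ground_truth = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "regulated": regulated,
            "direction": direction,
            "archetype": archetype,
            "true_kinase": kinase,
            "pi3k_dependent": pi3k_dep,
            "akt_dependent": akt_dep,
            "window_source": window_source,
            "effect_size_log2": signed_effect,
            "reversal_ly_true": np.where(regulated, rev_ly, np.nan),
            "reversal_mk_true": np.where(regulated, rev_mk, np.nan),
        }
    )
    return records, ground_truth
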