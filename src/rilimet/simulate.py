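"""Synthetic whole-thorax-irradiation (WTI) metabolomics cohorts.

The generator emulates a radiation-induced-lung-injury study design:
rats receiving 0/10/20/35 Gy whole-thorax irradiation, plasma sampled at
days 1/2/3/5 post-exposure and lung tissue at day 5, with group sizes
11/10/9/9, pooled QC injections, internal-standard channels and
completely-at-random missingness.

Measurement model (log scale)::

    log x(a, m, dose, day) = mu_m + u_a
                             + dir_m * amp_m * sigma_e * f(dose/dmax) * g(day)
                             + eps,      u_a ~ N(0, sigma_a^2),
                                         eps ~ N(0, sigma_e^2)

exponentiated to strictly positive abundances. ``f`` is the dose-response
shape (linear, saturating, or a 35-Gy-only step), ``g`` ramps linearly
from 0 at the effect's onset day to 1 at the latest sampling day, so that
post-onset trajectories are monotone. Amplitudes are expressed in units
of the residual log-SD at the highest dose and latest day, tying planted
effects directly to statistical power.

Internal-standard channels are constant-times-noise columns (the spiked
deuterated standards carry no biology), so IS normalization downstream is
exercised non-trivially. QC samples are drawn around the pooled study
mean of each channel with a prescribed coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .datamodel import SampleTable, write_sample_table

DOSE_SHAPES = ("linear", "saturating", "high_dose_only")


@dataclass(frozen=True)
class EffectSpec:
    """A planted dose/time effect for one metabolite.

    ``amplitude_sd`` is the maximum absolute log-scale shift in units of
    the residual log-SD, attained at the highest dose and latest day.
    Decoys have ``amplitude_sd = 0``.
    """

    metabolite_id: str
    chem_class: str
    direction: int
    amplitude_sd: float
    dose_shape: str
    onset_day: int
    name: str = ""
    acyl_chain: str | None = None

    def __post_init__(self):
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be >= 0")
        if self.dose_shape not in DOSE_SHAPES:
            raise ValueError(f"unknown dose_shape {self.dose_shape!r}")


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    Defaults are the emulated cohort design: doses 0/10/20/35 Gy with
    11/10/9/9 animals, plasma days 1/2/3/5, lung at day 5, residual
    log-SD 0.3, planted amplitude 3 residual-SD, 6 pooled QC injections
    at 5% analytical CV and 5% missingness.
    """

    doses_gy: tuple = (0.0, 10.0, 20.0, 35.0)
    n_per_dose: tuple = (11, 10, 9, 9)
    days: tuple = (1, 2, 3, 5)
    n_metabolites: int = 80
    n_planted_markers: int = 15
    amplitude_sd: float = 3.0
    effect_library: list = None
    residual_sd_log: float = 0.3
    animal_sd_log: float = 0.05
    qc_n: int = 6
    qc_rsd: float = 0.05
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.doses_gy) != len(self.n_per_dose):
            raise ValueError("doses_gy and n_per_dose must have equal length")
        if not self.doses_gy or not self.days:
            raise ValueError("dose and day lists must be nonempty")
        if self.n_planted_markers > self.n_metabolites:
            raise ValueError("n_planted_markers exceeds n_metabolites")
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.residual_sd_log <= 0:
            raise ValueError("residual_sd_log must be positive")


@dataclass
class CohortData:
    """One simulated cohort: lung at the terminal day, plasma per day,
    and the ground-truth planted effects."""

    lung: SampleTable
    plasma_by_day: dict
    truth: list
    config: SimConfig = None

    @property
    def planted_ids(self) -> list:
        return [e.metabolite_id for e in self.truth]

    def write_directory(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(self.lung, out, "lung_d5")
        for day, tab in sorted(self.plasma_by_day.items()):
            _write(tab, out, f"plasma_d{day}")
        with open(out / "truth.json", "w") as fh:
            json.dump([asdict(e) for e in self.truth], fh, indent=1)


def _write(table, out, stem):
    write_sample_table(table, out / f"{stem}_abundance.csv",
                       out / f"{stem}_samples.csv",
                       out / f"{stem}_metabolites.csv")


# ---------------------------------------------------------------------------
# effect library

# Archetype catalogue, in planting priority order. The first six are
# the regulation patterns characteristic of RILI: long-chain
# acylcarnitines rise from day 1; free carnitine, short-chain AC5:0,
# branched-chain amino acids, taurine-conjugated bile acids and urea fall
# with class-specific onsets. AC5:0 responds at the highest dose only
# (its lung change was confined to 35 Gy); the long-chain AC response
# saturates with dose (early, maintained). Later entries extend the
# catalogue with the acylcarnitine channels the CPT ratio statistics use
# and further lipid / amino-acid / bile-acid patterns.
#   (id, name, class, chain, direction, shape, onset_day)
_ARCHETYPES = [
    ("AC20:1", "acylcarnitine C20:1", "acylcarnitine", "C20:1", +1, "saturating", 1),
    ("carnitine", "carnitine", "other", "carnitine", -1, "linear", 2),
    ("AC5:0", "acylcarnitine C5:0", "acylcarnitine", "C5:0", -1, "high_dose_only", 2),
    ("Leu", "leucine", "amino_acid", None, -1, "linear", 3),
    ("TCA_bile", "taurocholic acid", "bile_acid", None, -1, "linear", 5),
    ("urea", "urea", "other", None, -1, "linear", 1),
    ("THDCA", "taurohyodeoxycholic acid", "bile_acid", None, -1, "linear", 5),
    ("T-a-MCA", "tauro-alpha-muricholic acid", "bile_acid", None, -1, "linear", 5),
    ("AC9:1", "acylcarnitine C9:1", "acylcarnitine", "C9:1", -1, "linear", 3),
    ("AC16:0", "acylcarnitine C16:0", "acylcarnitine", "C16:0", +1, "saturating", 1),
    ("AC18:1", "acylcarnitine C18:1", "acylcarnitine", "C18:1", +1, "saturating", 1),
    ("AC16:1", "acylcarnitine C16:1", "acylcarnitine", "C16:1", +1, "saturating", 1),
    ("AC18:0", "acylcarnitine C18:0", "acylcarnitine", "C18:0", +1, "saturating", 1),
    ("AC20:0", "acylcarnitine C20:0", "acylcarnitine", "C20:0", +1, "saturating", 1),
    ("AC13:1", "acylcarnitine C13:1", "acylcarnitine", "C13:1", +1, "saturating", 1),
    ("cholesterol", "cholesterol", "lipid", None, +1, "linear", 5),
    ("MG16:0", "palmitoylglycerol", "lipid", None, +1, "linear", 5),
    ("Val", "valine", "amino_acid", None, -1, "linear", 3),
    ("Ile", "isoleucine", "amino_acid", None, -1, "linear", 3),
    ("Arg", "arginine", "amino_acid", None, -1, "linear", 2),
    ("Indols", "indoxyl sulfate", "organic_acid", None, -1, "high_dose_only", 5),
    ("Hybs", "4-hydroxybenzenesulfonic acid", "organic_acid", None, -1, "high_dose_only", 5),
    ("TUDCA", "tauroursodeoxycholic acid", "bile_acid", None, -1, "linear", 5),
    ("Trp", "tryptophan", "amino_acid", None, -1, "linear", 3),
    ("Pro", "proline", "amino_acid", None, -1, "linear", 3),
]

N_MANDATORY = 6

# Always-present unplanted channels: acetylcarnitine is the CPT2 ratio
# denominator and must be measured even when not regulated.
_FIXED_DECOYS = [
    ("AC2", "acetylcarnitine", "acylcarnitine", "C2"),
]

# Baseline medians chosen so control-group CPT ratio medians land near
# the magnitudes the surrogate ratios take in rat lung (CPT1 ~ 155,
# CPT2 ~ 0.004).
_BASELINES = {"carnitine": 1.55e4, "AC16:1": 50.0, "AC18:0": 50.0,
              "AC16:0": 100.0, "AC18:1": 100.0, "AC2": 5.0e4}


def default_effect_library(n_metabolites: int, n_planted: int,
                           seed: int, amplitude_sd: float = 3.0,
                           days: tuple = (1, 2, 3, 5)) -> list:
    """Build the default effect library: ``n_planted`` archetypes with
    nonzero amplitude (the six mandatory regulation patterns first),
    the remaining metabolites as amplitude-0 decoys.

    Deterministic given ``seed``; the seed only randomizes nothing today
    but keeps the signature stable for future randomized catalogues.
    """
    if n_planted < N_MANDATORY:
        raise ValueError(f"n_planted must be >= {N_MANDATORY} to cover the "
                         "mandatory archetypes")
    if n_planted > len(_ARCHETYPES):
        raise ValueError(f"at most {len(_ARCHETYPES)} archetypes available")
    if n_metabolites < len(_ARCHETYPES) + len(_FIXED_DECOYS):
        raise ValueError("n_metabolites too small for the archetype "
                         f"catalogue ({len(_ARCHETYPES) + len(_FIXED_DECOYS)})")
    max_day = max(days)
    specs = []
    for i, (mid, name, cls, chain, direction, shape, onset) in enumerate(
            _ARCHETYPES):
        amp = amplitude_sd if i < n_planted else 0.0
        onset = min(onset, max_day)
        specs.append(EffectSpec(mid, cls, direction, amp, shape, onset,
                                name=name, acyl_chain=chain))
    for mid, name, cls, chain in _FIXED_DECOYS:
        specs.append(EffectSpec(mid, cls, +1, 0.0, "linear", max_day,
                                name=name, acyl_chain=chain))
    n_generic = n_metabolites - len(specs)
    rng = np.random.default_rng(seed)
    classes = rng.choice(["lipid", "amino_acid", "organic_acid", "other"],
                         size=n_generic)
    for j in range(n_generic):
        specs.append(EffectSpec(f"M{j + 1:04d}", str(classes[j]), +1, 0.0,
                                "linear", max_day, name=f"metabolite {j + 1}"))
    return specs


# ---------------------------------------------------------------------------
# cohort simulation

def _dose_response(shape: str, frac: np.ndarray) -> np.ndarray:
    if shape == "linear":
        return frac
    if shape == "saturating":
        return (1.0 - np.exp(-3.0 * frac)) / (1.0 - np.exp(-3.0))
    if shape == "high_dose_only":
        return (frac >= 0.999).astype(float)
    raise ValueError(shape)


def _time_ramp(day: int, onset: int, max_day: int) -> float:
    """0 before onset, half amplitude at the onset day (the effect is
    already detectable when it first appears), linear ramp to 1 at the
    latest sampling day."""
    if day < onset:
        return 0.0
    if max_day == onset:
        return 1.0
    return 0.5 + 0.5 * (day - onset) / (max_day - onset)


_IS_CHANNELS = ("IS_1", "IS_2")
_IS_LEVEL = 5.0e3
_IS_CV = 0.05


def _metabolite_meta(specs: list) -> pd.DataFrame:
    rows = {}
    for i, e in enumerate(specs):
        rows[e.metabolite_id] = {"name": e.name or e.metabolite_id,
                                 "chem_class": e.chem_class,
                                 "acyl_chain": e.acyl_chain,
                                 "is_channel": _IS_CHANNELS[i % 2]}
    for c in _IS_CHANNELS:
        rows[c] = {"name": c, "chem_class": "other", "acyl_chain": None,
                   "is_channel": None}
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate one cohort under ``config``; bit-reproducible from
    ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    specs = cfg.effect_library
    if specs is None:
        specs = default_effect_library(cfg.n_metabolites,
                                       cfg.n_planted_markers, cfg.seed,
                                       amplitude_sd=cfg.amplitude_sd,
                                       days=cfg.days)
    mids = [e.metabolite_id for e in specs]
    n_m = len(mids)
    max_day = max(cfg.days)
    dmax = max(cfg.doses_gy)

    # per-metabolite baselines (log scale), with anchored ratio channels
    mu = np.log(1.0e4) + rng.normal(0.0, 1.0, size=n_m)
    for i, mid in enumerate(mids):
        if mid in _BASELINES:
            mu[i] = np.log(_BASELINES[mid])

    # animals: one roster shared across tissues and days
    animals, doses_of = [], []
    for dose, n in zip(cfg.doses_gy, cfg.n_per_dose):
        for k in range(n):
            animals.append(f"R{int(dose):02d}_{k + 1:02d}")
            doses_of.append(float(dose))
    doses_of = np.asarray(doses_of)
    u = rng.normal(0.0, cfg.animal_sd_log, size=len(animals))

    shift = np.zeros((len(animals), n_m))  # per-dose effect template, filled per day

    def make_table(tissue: str, day: int) -> SampleTable:
        frac = doses_of / dmax if dmax > 0 else np.zeros_like(doses_of)
        for j, e in enumerate(specs):
            if e.amplitude_sd == 0:
                shift[:, j] = 0.0
                continue
            g = _time_ramp(day, e.onset_day, max_day)
            shift[:, j] = (e.direction * e.amplitude_sd * cfg.residual_sd_log
                           * _dose_response(e.dose_shape, frac) * g)
        eps = rng.normal(0.0, cfg.residual_sd_log, size=(len(animals), n_m))
        logx = mu[None, :] + u[:, None] + shift + eps
        x = np.exp(logx)
        # internal standards: constant level times analytical noise only
        is_vals = _IS_LEVEL * np.exp(
            rng.normal(0.0, _IS_CV, size=(len(animals), len(_IS_CHANNELS))))
        sids = [f"{tissue}_d{day}_{a}" for a in animals]
        ab = pd.DataFrame(np.hstack([x, is_vals]), index=sids,
                          columns=mids + list(_IS_CHANNELS))
        # pooled QC injections around the study mean, lognormal with the
        # prescribed CV
        sigma_qc = np.sqrt(np.log1p(cfg.qc_rsd ** 2))
        pooled = ab.mean(axis=0).to_numpy()
        qc = pooled[None, :] * np.exp(
            rng.normal(0.0, sigma_qc, size=(cfg.qc_n, ab.shape[1]))
            - sigma_qc ** 2 / 2.0)
        qsids = [f"{tissue}_d{day}_QC{k + 1:02d}" for k in range(cfg.qc_n)]
        ab = pd.concat([ab, pd.DataFrame(qc, index=qsids,
                                         columns=ab.columns)])
        # MCAR missingness among study samples, measured channels only
        if cfg.missing_rate > 0:
            mask = rng.random((len(animals), n_m)) < cfg.missing_rate
            block = ab.iloc[:len(animals), :n_m].to_numpy()
            block[mask] = np.nan
            ab.iloc[:len(animals), :n_m] = block
        weights = (rng.normal(20.0, 2.0, size=len(animals)).clip(min=5.0)
                   if tissue == "lung" else np.full(len(animals), np.nan))
        sm = pd.DataFrame({
            "animal_id": animals + [f"QC{k + 1:02d}" for k in range(cfg.qc_n)],
            "tissue": tissue,
            "dose_gy": list(doses_of) + [np.nan] * cfg.qc_n,
            "day": float(day),
            "role": ["study"] * len(animals) + ["qc"] * cfg.qc_n,
            "tissue_weight_mg": list(weights) + (
                [20.0] * cfg.qc_n if tissue == "lung"
                else [np.nan] * cfg.qc_n),
        }, index=ab.index)
        return SampleTable(ab, sm, _metabolite_meta(specs))

    plasma = {day: make_table("plasma", day) for day in cfg.days}
    lung = make_table("lung", max_day)
    truth = [e for e in specs if e.amplitude_sd > 0]
    return CohortData(lung=lung, plasma_by_day=plasma, truth=truth,
                      config=cfg)
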