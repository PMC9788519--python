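"""Synthetic serum-metabolome cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* log-normal, strictly positive concentrations for 41 metabolites,
  112 lipoprotein parameters and 3 spectral inflammation bins
  (GlycA, GlycB, SPC), with equicorrelated lipoprotein blocks on the
  log scale (one block per subclass, one per main fraction);
* an acute-disease panel whose variables are shifted by a configured
  number of *control-group standard deviations* (on the log scale, so the
  downstream covariate-adjusted screen is unbiased), with configurable sign;
* per-subject longitudinal recovery: a recovery time ``T`` drawn from a
  generalized extreme value law (defaults are the study-scale parameters
  location 62.44 d, scale 30.16 d, shape 0.34), modulated by age and
  clinical severity, with the panel displacement shrinking linearly from
  the full acute effect at day 0 to zero at day ``T``;
* sparse sampling days drawn from the study's follow-up day bins
  ((0,7], (7,14], (14,30], (30,60], >60 capped at 120);
* a 13-marker cytokine/chemokine panel with acute up-regulation decaying
  linearly from day 8, the MCP-1 decay duration correlated with the
  metabolic recovery time;
* simple Gaussian-peak 1D spectra for exercising spectral binning.

Ground truth (true recovery day, planted panel, outlier row ids) is carried
alongside so every downstream estimator can be checked against it.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .sampletable import SampleTable

__all__ = [
    "GeneratorConfig",
    "Spectrum",
    "CYTOKINE_PANEL",
    "default_panel_38",
    "default_panel_14",
    "metabolite_names",
    "lipoprotein_names",
    "inflammation_names",
    "generate_population",
    "generate_longitudinal",
    "generate_cytokines",
    "generate_spectrum",
    "inject_outliers",
]

# --------------------------------------------------------------------------
# variable naming
# --------------------------------------------------------------------------

_METABOLITES_41 = [
    "Glucose", "Lactate", "Alanine", "Glutamine", "Glutamate", "Glycine",
    "Histidine", "Isoleucine", "Leucine", "Lysine", "Methionine",
    "Phenylalanine", "Tyrosine", "Valine", "Threonine", "Creatine",
    "Creatinine", "Citrate", "Acetate", "Acetone", "Acetoacetate",
    "3-Hydroxybutyrate", "Pyruvate", "Formate", "Choline", "Ornithine",
    "Proline", "Sarcosine", "Serine", "Asparagine", "Aspartate",
    "Tryptophan", "Succinate", "Methanol", "Ethanol", "Glycerol",
    "Dimethylsulfone", "Dimethylglycine", "TMAO", "2-Aminobutyrate",
    "2-Oxoglutarate",
]

_SUBCLASSES = ["V1", "V2", "V3", "V4", "V5", "ID",
               "L1", "L2", "L3", "L4", "L5", "L6",
               "H1", "H2", "H3", "H4"]
_SUB_ANALYTES = ["TG", "CH", "FC", "PL", "PN"]
_MAIN_FRACTIONS = ["VL", "LD", "HD", "TP"]
_MAIN_ANALYTES = ["TG", "CH", "FC", "PL", "PN", "A1", "A2", "AB"]

#: The 13-marker cytokine/chemokine panel measured in the study cohorts.
CYTOKINE_PANEL = [
    "IL-6", "IL-1RA", "IP-10", "MCP-1", "IL-1b", "IFN-g", "TNF-a",
    "IL-8", "IL-10", "IL-12p70", "IL-17A", "IL-18", "GM-CSF",
]


def metabolite_names(n: int) -> list[str]:
    names = list(_METABOLITES_41[:n])
    names += [f"Met{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def lipoprotein_names(n: int) -> list[str]:
    """Subclass-wise then main-fraction parameter codes (112 by default)."""
    names = [s + a for s in _SUBCLASSES for a in _SUB_ANALYTES]
    names += [f + a for f in _MAIN_FRACTIONS for a in _MAIN_ANALYTES]
    names += [f"Lip{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names[:n]


def inflammation_names(n: int) -> list[str]:
    base = ["GlycA", "GlycB", "SPC"]
    return (base + [f"InflBin{i}" for i in range(4, n + 1)])[:n]


def _default_lipo_blocks(n_lipo: int, rho: float = 0.5) -> list[tuple[int, float]]:
    """One block per subclass (5 analytes) and per main fraction (8)."""
    blocks: list[tuple[int, float]] = []
    left = n_lipo
    for size in [5] * len(_SUBCLASSES) + [8] * len(_MAIN_FRACTIONS):
        if left <= 0:
            break
        s = min(size, left)
        blocks.append((s, rho))
        left -= s
    if left > 0:
        blocks.append((left, rho))
    return blocks


# --------------------------------------------------------------------------
# informative panels
# --------------------------------------------------------------------------

def default_panel_38() -> list[tuple[str, float, int]]:
    """38-variable healthy-vs-acute discrimination panel.

    Mirrors the composition of the study's discrimination panel: amino acids
    and energy metabolites shifted in both directions, the three glycoprotein
    / phospholipid inflammation signals raised, triglyceride-rich VLDL
    parameters raised and HDL/ApoA-I parameters lowered.  Effects span
    0.7-2.0 control-SD; same-block pairs are kept weak enough that their
    pooled correlation stays well under the 0.8 pruning threshold.
    """
    up_met = [("Phenylalanine", 2.0), ("Glucose", 1.6), ("Glutamate", 1.4),
              ("Choline", 1.2), ("Lactate", 1.0), ("3-Hydroxybutyrate", 0.9),
              ("Pyruvate", 0.8)]
    down_met = [("Glutamine", 1.5), ("Histidine", 1.3), ("Lysine", 1.1),
                ("Alanine", 0.9), ("Tryptophan", 0.8)]
    up_infl = [("GlycA", 1.8), ("GlycB", 1.6), ("SPC", 1.4)]
    up_lip = [("V1TG", 2.0), ("V2TG", 1.7), ("V3TG", 1.4), ("V4TG", 1.1),
              ("V5TG", 0.8), ("VLTG", 1.8), ("TPTG", 1.5), ("V1CH", 0.9),
              ("IDTG", 1.0), ("L1TG", 0.7)]
    down_lip = [("H1CH", 1.9), ("H2CH", 1.6), ("H3CH", 1.3), ("H4CH", 1.0),
                ("HDCH", 1.7), ("H1PL", 0.9), ("H2PL", 0.7), ("HDA1", 1.2),
                ("TPA1", 1.4), ("L1CH", 0.8), ("LDCH", 1.1), ("L2CH", 0.75),
                ("L3FC", 0.85)]
    panel = [(n, e, +1) for n, e in up_met + up_infl + up_lip]
    panel += [(n, e, -1) for n, e in down_met + down_lip]
    assert len(panel) == 38
    return panel


def default_panel_14() -> list[tuple[str, float, int]]:
    """14-variable acute-vs-acute (lineage comparison) panel.

    Triglyceride-centred, matching the dominant between-wave difference;
    effects span 0.9-2.0 control-SD, keeping the weakest member's selection
    power near 1 at the n=115-per-class design (the effect-estimate SE
    there is ~0.14 SD against the 0.5-SD floor).
    """
    up = [("TPTG", 2.0), ("VLTG", 1.8), ("V1TG", 1.65), ("V2TG", 1.5),
          ("V3TG", 1.35), ("L1TG", 1.2), ("IDTG", 1.05), ("V1PL", 0.9)]
    down = [("H1TG", 1.7), ("Glucose", 1.55), ("Lactate", 1.4),
            ("Alanine", 1.25), ("H2TG", 1.1), ("L2TG", 0.95)]
    return [(n, e, +1) for n, e in up] + [(n, e, -1) for n, e in down]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Effects are expressed in units of the control group's *marginal*
    log-scale standard deviation (biological + analytical + covariate
    variance), so the downstream screen recovers them without bias.
    """

    n_controls: int = 400
    n_acute: int = 400
    n_metabolites: int = 41
    n_lipoproteins: int = 112
    n_inflammation_bins: int = 3
    #: (variable name, |effect| in control-SD units, sign in {-1, +1})
    informative_panel: list[tuple[str, float, int]] = field(default_factory=default_panel_38)
    #: lipoprotein correlation blocks as (size, within-block rho); applied in
    #: variable order to the lipoprotein section of the table
    block_structure: list[tuple[int, float]] | None = None
    #: within-correlation of the three inflammation bins
    inflammation_rho: float = 0.5
    # recovery-time law (generalized extreme value, evd sign convention)
    gev_location: float = 62.44
    gev_scale: float = 30.16
    gev_shape: float = 0.34
    age_range: tuple[float, float] = (25.0, 85.0)
    #: additive days of recovery per year of age (centred at the age mean)
    age_effect_on_recovery: float = 0.5
    #: label -> multiplicative recovery-time factor
    severity_classes: dict[str, float] = field(
        default_factory=lambda: {"mild-moderate": 1.0, "severe": 1.35})
    #: label -> sampling probability (same keys as severity_classes)
    severity_probs: dict[str, float] = field(
        default_factory=lambda: {"mild-moderate": 0.6, "severe": 0.4})
    #: follow-up day bins (lo, hi), days drawn as integers uniform in [lo, hi]
    sampling_bins: list[tuple[int, int]] = field(
        default_factory=lambda: [(1, 7), (8, 14), (15, 30), (31, 60), (61, 120)])
    #: per-bin probability that a subject contributes a sample to the bin
    sampling_probs: list[float] | None = None
    #: analytical (within-subject) coefficient of variation
    noise_cv: float = 0.10
    #: biological (between-subject) coefficient of variation
    biological_cv: float = 0.25
    #: age slope, in control-SD per year, applied to lipoprotein parameters
    age_covariate_sd_per_year: float = 0.008
    #: variable -> shift in control-SD units, positive = higher in males
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {"Creatinine": 0.5, "V1TG": 0.3, "H1CH": -0.3})
    # cytokine generator
    cytokine_markers: list[str] = field(default_factory=lambda: list(CYTOKINE_PANEL))
    #: marker -> acute fold elevation over the healthy mean
    cytokine_folds: dict[str, float] = field(
        default_factory=lambda: {"IL-1RA": 3.0, "IP-10": 4.0, "IL-6": 2.5, "MCP-1": 2.0})
    #: target Pearson correlation between the per-subject MCP-1 decay
    #: duration and the true metabolic recovery day
    mcp1_coupling: float = 0.8
    cytokine_decay_mean: float = 60.0
    cytokine_decay_sd: float = 25.0
    cytokine_cv: float = 0.40
    seed: int = 0

    # -- derived quantities ------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()
        if self.block_structure is None:
            self.block_structure = _default_lipo_blocks(self.n_lipoproteins)
        if self.sampling_probs is None:
            defaults = {(1, 7): 0.5, (8, 14): 0.4, (15, 30): 0.5,
                        (31, 60): 0.8, (61, 120): 0.6}
            self.sampling_probs = [defaults.get(tuple(b), 1.0) for b in self.sampling_bins]

    def validate(self) -> None:
        for fld in ("n_controls", "n_acute", "n_metabolites",
                    "n_lipoproteins", "n_inflammation_bins"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"{fld} must be >= 0, got {getattr(self, fld)}")
        for name, eff, sign in self.informative_panel:
            if not math.isfinite(eff) or eff < 0:
                raise ConfigError(f"informative_panel effect for {name!r} must be finite and >= 0")
            if sign not in (-1, 1):
                raise ConfigError(f"informative_panel sign for {name!r} must be -1 or +1")
        if self.block_structure is not None:
            for size, rho in self.block_structure:
                if not 0 <= rho < 1:
                    raise ConfigError(f"block_structure rho must be in [0,1), got {rho}")
                if size < 1:
                    raise ConfigError(f"block_structure size must be >= 1, got {size}")
        if not 0 <= self.inflammation_rho < 1:
            raise ConfigError(f"inflammation_rho must be in [0,1), got {self.inflammation_rho}")
        if self.gev_scale <= 0:
            raise ConfigError(f"gev_scale must be > 0, got {self.gev_scale}")
        if self.noise_cv < 0 or self.biological_cv < 0:
            raise ConfigError("noise_cv and biological_cv must be >= 0")
        if self.biological_cv == 0 and self.noise_cv == 0 and self.n_controls > 0:
            # a fully degenerate table cannot be standardized downstream,
            # but it is still a valid request; no error.
            pass
        if set(self.severity_classes) != set(self.severity_probs):
            raise ConfigError("severity_classes and severity_probs must share keys")
        if self.sampling_bins and any(lo > hi for lo, hi in self.sampling_bins):
            raise ConfigError("sampling_bins intervals must satisfy lo <= hi")
        unknown = set(self.cytokine_folds) - set(self.cytokine_markers)
        if unknown:
            raise ConfigError(f"cytokine_folds references unknown markers: {sorted(unknown)}")
        if not -1 <= self.mcp1_coupling <= 1:
            raise ConfigError(f"mcp1_coupling must be in [-1,1], got {self.mcp1_coupling}")

    # variable bookkeeping -------------------------------------------------
    def variable_names(self) -> list[str]:
        return (metabolite_names(self.n_metabolites)
                + lipoprotein_names(self.n_lipoproteins)
                + inflammation_names(self.n_inflammation_bins))

    def panel_dict(self) -> dict[str, float]:
        """Signed planted effect per panel variable (control-SD units)."""
        names = set(self.variable_names())
        for name, _, _ in self.informative_panel:
            if name not in names:
                raise ConfigError(f"informative_panel variable {name!r} not in variable set")
        return {name: sign * eff for name, eff, sign in self.informative_panel}

    @property
    def sigma_bio(self) -> float:
        return math.sqrt(math.log1p(self.biological_cv ** 2))

    @property
    def sigma_meas(self) -> float:
        return math.sqrt(math.log1p(self.noise_cv ** 2))


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly monotone ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise DataError("ppm and intensity must have equal length")
        if np.any(np.diff(self.ppm) <= 0):
            raise DataError("ppm axis must be strictly monotone increasing")
        if np.any(self.intensity < 0):
            raise DataError("intensity must be non-negative")


# --------------------------------------------------------------------------
# internal building blocks
# --------------------------------------------------------------------------

def _rng(config: GeneratorConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, salt])


def _name_scale(name: str, lo: float, hi: float) -> float:
    """Deterministic per-variable typical level from a stable name hash."""
    u = (zlib.crc32(name.encode()) % 10_000) / 10_000.0
    return math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))


def _base_levels(config: GeneratorConfig) -> np.ndarray:
    """log-scale location mu_v per variable (mmol/L, mg/dL, bin fraction)."""
    mus = []
    for name in metabolite_names(config.n_metabolites):
        mus.append(math.log(_name_scale(name, 0.05, 5.0)))
    for name in lipoprotein_names(config.n_lipoproteins):
        mus.append(math.log(_name_scale(name, 5.0, 150.0)))
    for name in inflammation_names(config.n_inflammation_bins):
        mus.append(math.log(_name_scale(name, 1e-3, 1e-2)))
    return np.asarray(mus)


def _block_index(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable block id (-1 = independent) and within-block rho."""
    p = config.n_metabolites + config.n_lipoproteins + config.n_inflammation_bins
    block = np.full(p, -1, dtype=int)
    rho = np.zeros(p)
    pos = config.n_metabolites
    bid = 0
    for size, r in config.block_structure:
        hi = min(pos + size, config.n_metabolites + config.n_lipoproteins)
        block[pos:hi] = bid
        rho[pos:hi] = r
        pos = hi
        bid += 1
        if pos >= config.n_metabolites + config.n_lipoproteins:
            break
    if config.n_inflammation_bins > 1 and config.inflammation_rho > 0:
        block[-config.n_inflammation_bins:] = bid
        rho[-config.n_inflammation_bins:] = config.inflammation_rho
    return block, rho


def _covariate_sd(config: GeneratorConfig, names: list[str]) -> np.ndarray:
    """Per-variable SD contribution of the age/sex covariate effects.

    Expressed as a multiple of the bio+meas SD (self-consistent closure of
    the 'effects in marginal SD units' convention: covariate effects are
    also stated in marginal SD units, giving marginal^2 = base^2 * (1 +
    age^2 + sex^2) with age/sex terms in marginal units).
    """
    lo, hi = config.age_range
    age_sd = (hi - lo) / math.sqrt(12.0)
    frac = np.zeros(len(names))
    lip = set(lipoprotein_names(config.n_lipoproteins))
    for i, name in enumerate(names):
        f2 = 0.0
        if name in lip:
            f2 += (config.age_covariate_sd_per_year * age_sd) ** 2
        if name in config.sex_effects:
            f2 += (config.sex_effects[name] / 2.0) ** 2
        frac[i] = f2
    return frac  # variance fraction in marginal-SD units


#: log-SD used as the effect unit when all noise is switched off, so that
#: planted displacements stay visible in a fully deterministic table; equals
#: the base log-SD of the default noise settings (bio CV 0.25, meas CV 0.10).
_REFERENCE_SIGMA = math.sqrt(math.log1p(0.25 ** 2) + math.log1p(0.10 ** 2))


def _marginal_sigma(config: GeneratorConfig, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(marginal log-SD, covariate variance fraction) per variable."""
    base = math.sqrt(config.sigma_bio ** 2 + config.sigma_meas ** 2)
    if base == 0.0:
        base = _REFERENCE_SIGMA
    f2 = _covariate_sd(config, names)
    # marginal^2 = base^2 + (covariate effects in marginal units)^2 * marginal^2
    f2 = np.minimum(f2, 0.99)
    marginal = base / np.sqrt(1.0 - f2)
    return marginal, f2


def _draw_subject_scores(config: GeneratorConfig, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Between-subject standard scores with block correlation, n x p."""
    p = config.n_metabolites + config.n_lipoproteins + config.n_inflammation_bins
    block, rho = _block_index(config)
    z = rng.standard_normal((n, p))
    nblocks = block.max() + 1 if p else 0
    if nblocks > 0:
        g = rng.standard_normal((n, nblocks))
        mask = block >= 0
        r = rho[mask]
        z[:, mask] = (np.sqrt(r) * g[:, block[mask]]
                      + np.sqrt(1.0 - r) * z[:, mask])
    return z


def _subject_metadata(config: GeneratorConfig, n: int, prefix: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.age_range
    ages = np.round(rng.uniform(lo, hi, size=n), 1)
    sexes = rng.choice(["M", "F"], size=n)
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i:05d}" for i in range(1, n + 1)],
        "age": ages,
        "sex": sexes,
    })


def _covariate_shift(config: GeneratorConfig, names: list[str],
                     meta: pd.DataFrame, marginal: np.ndarray) -> np.ndarray:
    """Additive log-scale shift from age and sex, n x p."""
    lo, hi = config.age_range
    mid = (lo + hi) / 2.0
    n = len(meta)
    shift = np.zeros((n, len(names)))
    lip = set(lipoprotein_names(config.n_lipoproteins))
    age_c = meta["age"].to_numpy() - mid
    is_m = (meta["sex"] == "M").to_numpy().astype(float) - 0.5
    for j, name in enumerate(names):
        s = 0.0 * age_c
        if name in lip:
            s = s + config.age_covariate_sd_per_year * age_c
        if name in config.sex_effects:
            s = s + config.sex_effects[name] * is_m
        shift[:, j] = s * marginal[j]
    return shift


_EPOCH_HC = pd.Timestamp("2019-06-01")
_EPOCH_COVID = pd.Timestamp("2020-04-01")


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def generate_population(config: GeneratorConfig) -> SampleTable:
    """Cross-sectional cohort: ``n_controls`` healthy + ``n_acute`` acute.

    Acute rows have every informative-panel variable shifted by its
    configured effect (control-SD units on the log scale) with its sign;
    all other variables are identically distributed in both groups.
    """
    names = config.variable_names()
    panel = config.panel_dict()
    mu = _base_levels(config)
    marginal, _ = _marginal_sigma(config, names)
    n_hc, n_ac = config.n_controls, config.n_acute
    rng = _rng(config, salt=1)

    meta_hc = _subject_metadata(config, n_hc, "HC", rng)
    meta_ac = _subject_metadata(config, n_ac, "AC", rng)
    meta = pd.concat([meta_hc, meta_ac], ignore_index=True)
    cohort = np.array(["HC"] * n_hc + ["AC"] * n_ac)

    z = _draw_subject_scores(config, n_hc + n_ac, rng)
    eps = rng.standard_normal((n_hc + n_ac, len(names)))
    logx = (mu[None, :]
            + _covariate_shift(config, names, meta, marginal)
            + config.sigma_bio * z
            + config.sigma_meas * eps)
    effect = np.array([panel.get(v, 0.0) for v in names])
    logx[n_hc:, :] += effect[None, :] * marginal[None, :]

    sev_labels = list(config.severity_classes)
    sev_p = np.array([config.severity_probs[k] for k in sev_labels], dtype=float)
    sev_p = sev_p / sev_p.sum() if sev_p.sum() > 0 else np.full(len(sev_p), 1 / len(sev_p))
    severity = np.array(["none"] * n_hc
                        + list(rng.choice(sev_labels, size=n_ac, p=sev_p)))
    hosp_offsets = rng.integers(0, 240, size=n_ac)
    coll_delay = rng.integers(0, 4, size=n_ac)
    hosp_dates = np.array([_EPOCH_COVID + pd.Timedelta(days=int(d)) for d in hosp_offsets],
                          dtype=object)
    df = pd.DataFrame({
        "sample_id": [f"{s}_0" for s in meta["subject_id"]],
        "subject_id": meta["subject_id"],
        "cohort": cohort,
        "collection_date": (
            [_EPOCH_HC + pd.Timedelta(days=int(d)) for d in rng.integers(0, 180, size=n_hc)]
            + [hosp_dates[i] + pd.Timedelta(days=int(coll_delay[i])) for i in range(n_ac)]),
        "hospitalization_date": [pd.NaT] * n_hc + list(hosp_dates),
        "covid_report_date": [pd.NaT] * (n_hc + n_ac),
        "age": meta["age"],
        "sex": meta["sex"],
        "severity": severity,
        "vaccinated": rng.random(n_hc + n_ac) < 0.3,
        "true_recovery_day": [np.nan] * (n_hc + n_ac),
    })
    values = pd.DataFrame(np.exp(logx), columns=names, index=df.index)
    df = pd.concat([df, values], axis=1)
    return SampleTable(df, names)


def _draw_recovery_days(config: GeneratorConfig, meta: pd.DataFrame,
                        severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """GEV recovery times, modulated by severity (x) and age (+ days/yr)."""
    n = len(meta)
    # evd convention: positive shape = heavy right tail; scipy c = -shape
    t = stats.genextreme.rvs(-config.gev_shape, loc=config.gev_location,
                             scale=config.gev_scale, size=n, random_state=rng)
    mult = np.array([config.severity_classes[s] for s in severity])
    lo, hi = config.age_range
    mid = (lo + hi) / 2.0
    t = t * mult + config.age_effect_on_recovery * (meta["age"].to_numpy() - mid)
    return np.maximum(t, 1.0)


def generate_longitudinal(config: GeneratorConfig) -> SampleTable:
    """Longitudinal acute subjects: day-0 acute sample plus sparse follow-ups.

    Per subject a true recovery day ``T`` is drawn from the configured GEV
    law (severity- and age-modulated); panel displacement shrinks linearly
    from the full acute effect at day 0 to zero at day ``T`` and stays at
    zero thereafter.  ``true_recovery_day`` is recorded on every row.
    """
    if not config.sampling_bins:
        raise ConfigError("sampling_bins must be non-empty for longitudinal generation")
    # Gumbel (shape->0) and Weibull/Frechet shapes are all supported by the
    # GEV family itself; a non-finite parameter is the only violation.
    if not (math.isfinite(config.gev_location) and math.isfinite(config.gev_shape)):
        raise ConfigError("gev_location and gev_shape must be finite")

    names = config.variable_names()
    panel = config.panel_dict()
    mu = _base_levels(config)
    marginal, _ = _marginal_sigma(config, names)
    n = config.n_acute
    rng = _rng(config, salt=2)

    meta = _subject_metadata(config, n, "RE", rng)
    sev_labels = list(config.severity_classes)
    sev_p = np.array([config.severity_probs[k] for k in sev_labels], dtype=float)
    sev_p = sev_p / sev_p.sum() if sev_p.sum() > 0 else np.full(len(sev_p), 1 / len(sev_p))
    severity = rng.choice(sev_labels, size=n, p=sev_p)
    recovery = _draw_recovery_days(config, meta, severity, rng)
    vaccinated = rng.random(n) < 0.3
    hosp_offsets = rng.integers(0, 240, size=n)
    first_delay = rng.integers(0, 4, size=n)  # first sample <= 7 d post-admission

    z_subj = _draw_subject_scores(config, n, rng)
    effect = np.array([panel.get(v, 0.0) for v in names])

    rows = []
    logxs = []
    for i in range(n):
        days = [0]
        for (lo, hi), prob in zip(config.sampling_bins, config.sampling_probs):
            if rng.random() < prob:
                days.append(int(rng.integers(lo, hi + 1)))
        days = sorted(set(days))
        hosp = _EPOCH_COVID + pd.Timedelta(days=int(hosp_offsets[i]))
        first = hosp + pd.Timedelta(days=int(first_delay[i]))
        for k, d in enumerate(days):
            f = max(0.0, 1.0 - d / recovery[i])
            eps = rng.standard_normal(len(names))
            logx = (mu + config.sigma_bio * z_subj[i]
                    + config.sigma_meas * eps
                    + f * effect * marginal)
            logxs.append(logx)
            rows.append({
                "sample_id": f"{meta['subject_id'][i]}_{k}",
                "subject_id": meta["subject_id"][i],
                "cohort": "AC" if d == 0 else "RE",
                "collection_date": first + pd.Timedelta(days=int(d)),
                "hospitalization_date": hosp,
                "covid_report_date": pd.NaT,
                "age": meta["age"][i],
                "sex": meta["sex"][i],
                "severity": severity[i],
                "vaccinated": vaccinated[i],
                "true_recovery_day": recovery[i],
            })
    df = pd.DataFrame(rows)
    cov = _covariate_shift(config, names,
                           df[["age", "sex"]].assign(age=df["age"].astype(float)),
                           marginal)
    logx = np.asarray(logxs) + cov
    values = pd.DataFrame(np.exp(logx), columns=names, index=df.index)
    df = pd.concat([df, values], axis=1)
    return SampleTable(df, names)


def generate_cytokines(config: GeneratorConfig, samples: SampleTable) -> pd.DataFrame:
    """13-marker cytokine panel for the given samples (long format).

    Acute rows carry the configured fold elevations, decaying linearly from
    day 8 back to the healthy mean; the per-subject MCP-1 decay duration is
    coupled to ``true_recovery_day`` at the configured correlation.
    Healthy rows (no day label) are drawn from the baseline law.

    Returns a DataFrame with columns sample_id, subject_id, marker, level,
    day, decay_days (the generated per-subject-marker decay duration).
    """
    df = samples.data
    covid = df["cohort"].isin(["AC", "RE", "NHR"])
    if covid.any() and "days_since_covid" not in df.columns:
        raise DataError("samples need day labels (run assign_days_since_covid first)")
    rng = _rng(config, salt=3)
    markers = config.cytokine_markers
    sigma = math.sqrt(math.log1p(config.cytokine_cv ** 2))
    base = {m: _name_scale("cyt:" + m, 10.0, 500.0) for m in markers}

    subjects = df["subject_id"].unique()
    subj_idx = {s: i for i, s in enumerate(subjects)}
    z_subj = rng.standard_normal((len(subjects), len(markers)))

    # per-subject decay durations; MCP-1 coupled to the true recovery day
    t_true = df.groupby("subject_id")["true_recovery_day"].first()
    t_vals = t_true.to_numpy(dtype=float)
    has_t = np.isfinite(t_vals)
    t_std = np.zeros(len(subjects))
    if has_t.sum() >= 2 and np.nanstd(t_vals[has_t]) > 0:
        t_std[has_t] = ((t_vals[has_t] - np.nanmean(t_vals[has_t]))
                        / np.nanstd(t_vals[has_t]))
    decay = {}
    rho = config.mcp1_coupling
    for m in markers:
        eps = rng.standard_normal(len(subjects))
        if m == "MCP-1":
            zd = rho * t_std + math.sqrt(max(0.0, 1 - rho ** 2)) * eps
        else:
            zd = eps
        decay[m] = np.maximum(5.0, config.cytokine_decay_mean
                              + config.cytokine_decay_sd * zd)

    day = df["days_since_covid"] if "days_since_covid" in df.columns else pd.Series(
        [np.nan] * len(df), index=df.index)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        sid = row.subject_id
        si = subj_idx[sid]
        d = day.iloc[i]
        is_covid = row.cohort in ("AC", "RE")
        for k, m in enumerate(markers):
            lvl = base[m] * math.exp(sigma * z_subj[si, k]
                                     + sigma * 0.4 * rng.standard_normal())
            if is_covid and np.isfinite(d):
                fold = config.cytokine_folds.get(m, 1.0)
                if d <= 8:
                    mult = fold
                else:
                    mult = 1.0 + (fold - 1.0) * max(0.0, 1.0 - (d - 8) / decay[m][si])
                lvl *= mult
            out.append((row.sample_id, sid, m, lvl,
                        float(d) if np.isfinite(d) else np.nan, decay[m][si]))
    return pd.DataFrame(out, columns=["sample_id", "subject_id", "marker",
                                      "level", "day", "decay_days"])


def generate_spectrum(config: GeneratorConfig,
                      peaks: list[tuple[float, float, float]],
                      n_points: int = 9001,
                      baseline_noise: float = 0.0) -> Spectrum:
    """Sum of Gaussian peaks (center ppm, width ppm, area) on a uniform grid."""
    for center, width, _area in peaks:
        if width <= 0:
            raise ConfigError(f"peak width must be > 0, got {width}")
        if not 0.5 <= center <= 9.5:
            raise ConfigError(f"peak center {center} outside the 0.5-9.5 ppm range")
    ppm = np.linspace(0.5, 9.5, n_points)
    intensity = np.zeros_like(ppm)
    for center, width, area in peaks:
        intensity += area / (width * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((ppm - center) / width) ** 2)
    if baseline_noise > 0:
        rng = _rng(config, salt=4)
        intensity += np.abs(baseline_noise * rng.standard_normal(len(ppm)))
    return Spectrum(ppm, intensity)


def inject_outliers(samples: SampleTable, n_outliers: int, magnitude: float,
                    seed: int = 0) -> tuple[SampleTable, list[str]]:
    """Displace ``n_outliers`` rows by ``magnitude`` raw-scale SD upward in
    every variable; returns the modified copy and the displaced sample ids."""
    if n_outliers > len(samples):
        raise DataError(f"n_outliers={n_outliers} exceeds table size {len(samples)}")
    out = samples.copy()
    if n_outliers == 0:
        return out, []
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 5])
    idx = rng.choice(len(out.data), size=n_outliers, replace=False)
    sds = out.data[out.variables].std(axis=0, ddof=1).to_numpy()
    block = out.data.loc[:, out.variables].to_numpy(dtype=float)
    p = len(out.variables)
    for row in idx:
        # non-negative direction, distinct per row, so multiple outliers do
        # not pile up into a dense cluster of their own
        u = np.abs(rng.standard_normal(p))
        u *= math.sqrt(p) / np.linalg.norm(u)
        block[row, :] += magnitude * sds * u
    out.data.loc[:, out.variables] = block
    ids = out.data.loc[idx, "sample_id"].tolist()
    return out, ids
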