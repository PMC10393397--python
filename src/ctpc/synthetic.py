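"""Synthetic environments, cardiac traces, phylogenies and trait cohorts.

Everything downstream of this module can be exercised against known ground
truth: diurnally cycling intertidal temperature regimes, ramped heating
traces whose beat rate follows a Sharpe-Schoolfield curve and flatlines above
a true upper lethal temperature (ULT), pure-birth phylogenies with Brownian
trait evolution plus a habitat effect, and trait cohorts with a prescribed
between-individual dispersion structure.

All randomness flows through one explicitly passed seed / NumPy generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.ndimage import uniform_filter1d

from .cardiotrace import CardiacTrace
from .tpc import (
    CELSIUS_TO_KELVIN,
    K_BOLTZ,
    SSParams,
    ss_rate,
    topt_closed_form,
)

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Environmental temperature regimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentPreset:
    """Summary statistics of a habitat thermal regime.

    The generator reproduces the stated mean and maximum exactly; the
    waveform (diurnal sinusoid plus midday heat pulses) is a plausible shape,
    not a measured one.
    """

    name: str
    mean_C: float
    max_C: float
    period_h: float = 24.0
    tidal_mod: bool = False

    def __post_init__(self) -> None:
        if self.max_C < self.mean_C:
            raise ValueError(f"{self.name}: max_C must be >= mean_C")
        if not self.period_h > 0:
            raise ValueError(f"{self.name}: period_h must be positive")


#: Sun-exposed upper rocky shore in the tropics: hot, highly variable.
ROCKY_SHORE = EnvironmentPreset("rocky_shore", mean_C=31.8, max_C=51.3)

#: Shaded mangrove trunk: mild, stable, tidally modulated.
MANGROVE = EnvironmentPreset("mangrove", mean_C=27.7, max_C=33.2, tidal_mod=True)


def simulate_environment(
    preset: EnvironmentPreset,
    days: int = 30,
    step_min: int = 10,
    seed: RngLike = 0,
) -> pd.DataFrame:
    """Temperature logger series (columns ``time_h``, ``temp_C``).

    A diurnal sinusoid plus half-day solar heat pulses with lognormal daily
    amplitude (optionally modulated on the ~12.4 h semidiurnal tidal cycle),
    affinely calibrated so the series mean equals ``preset.mean_C`` and the
    maximum equals ``preset.max_C`` exactly. Deterministic under a fixed seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if (24 * 60) % step_min != 0:
        raise ValueError("step_min must divide the day evenly")
    n = days * 24 * 60 // step_min
    t_h = np.arange(n) * step_min / 60.0
    if preset.max_C == preset.mean_C:
        return pd.DataFrame({"time_h": t_h, "temp_C": np.full(n, preset.mean_C)})

    rng = _rng(seed)
    base = -np.cos(2 * np.pi * (t_h % preset.period_h) / preset.period_h)
    day_idx = (t_h // 24).astype(int)
    daily_amp = rng.lognormal(mean=0.0, sigma=0.45, size=days)[day_idx]
    hour = t_h % 24.0
    pulse = daily_amp * np.exp(-0.5 * ((hour - 13.0) / 2.2) ** 2)
    if preset.tidal_mod:
        pulse = pulse * 0.5 * (1.0 + np.sin(2 * np.pi * t_h / 12.42))
    noise = uniform_filter1d(rng.normal(0.0, 0.35, n), size=max(3, 60 // step_min))
    raw = base + 2.2 * pulse + noise

    centered = raw - raw.mean()
    temp = preset.mean_C + centered * (preset.max_C - preset.mean_C) / centered.max()
    return pd.DataFrame({"time_h": t_h, "temp_C": temp})


def acclimation_cycle(group: str, days: int = 1, step_min: int = 10) -> pd.DataFrame:
    """Deterministic laboratory acclimation temperature program.

    ``"cool"``: 12 h at 27 C and 12 h at 30 C. ``"hot"``: 6 h rising 27->40 C,
    6 h falling 40->27 C, then 12 h at 27 C.
    """
    if (24 * 60) % step_min != 0:
        raise ValueError("step_min must divide the day evenly")
    n_day = 24 * 60 // step_min
    hour = np.arange(n_day) * step_min / 60.0
    if group == "cool":
        temp_day = np.where(hour < 12.0, 27.0, 30.0)
    elif group == "hot":
        temp_day = np.where(
            hour < 6.0, 27.0 + (40.0 - 27.0) * hour / 6.0,
            np.where(hour < 12.0, 40.0 - (40.0 - 27.0) * (hour - 6.0) / 6.0, 27.0),
        )
    else:
        raise ValueError(f"unknown acclimation group {group!r} (use 'cool' or 'hot')")
    temp = np.tile(temp_day, days)
    t_h = np.arange(days * n_day) * step_min / 60.0
    return pd.DataFrame({"time_h": t_h, "temp_C": temp})


# ---------------------------------------------------------------------------
# Cardiac traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RampProtocol:
    """Linear heating protocol of the cardiac assay."""

    start_C: float = 30.0
    end_C: float = 65.0
    rate_C_per_min: float = 0.25
    sample_hz: float = 40.0

    def __post_init__(self) -> None:
        if self.end_C <= self.start_C:
            raise ValueError("end_C must exceed start_C")
        if not self.rate_C_per_min > 0:
            raise ValueError("rate_C_per_min must be positive")
        if not self.sample_hz > 0:
            raise ValueError("sample_hz must be positive")

    @property
    def duration_s(self) -> float:
        return (self.end_C - self.start_C) / self.rate_C_per_min * 60.0

    def temp_at(self, t_s) -> np.ndarray:
        return self.start_C + self.rate_C_per_min / 60.0 * np.asarray(t_s, float)


@dataclass(frozen=True)
class TrueTraits:
    """Generative ground truth for one individual.

    ``depression_cap`` models resting metabolic depression: below
    ``depression_onset_C`` the beat rate is capped at this ceiling, producing
    the temperature-insensitive low-temperature plateau seen in some
    intertidal gastropods.
    """

    r_tref: float  # bpm at the reference temperature
    E: float  # activation energy, eV
    Eh: float  # deactivation energy, eV
    Th: float  # half-inactivation temperature, K
    ULT_true: float  # deg C
    depression_cap: Optional[float] = None  # bpm
    depression_onset_C: float = 40.0

    def __post_init__(self) -> None:
        ss = self.ss_params  # validates r_tref > 0 and Eh > E > 0
        if self.ULT_true <= topt_closed_form(ss):
            raise ValueError("ULT_true must exceed the curve's optimum temperature")

    @property
    def ss_params(self) -> SSParams:
        return SSParams(self.r_tref, self.E, self.Eh, self.Th)

    def rate_bpm(self, temp_C) -> np.ndarray:
        """True instantaneous beat rate: capped Sharpe-Schoolfield, 0 above ULT."""
        temp_C = np.asarray(temp_C, dtype=float)
        r = np.asarray(ss_rate(self.ss_params, temp_C), dtype=float)
        if self.depression_cap is not None:
            r = np.where(temp_C < self.depression_onset_C,
                         np.minimum(r, self.depression_cap), r)
        r = np.where(temp_C >= self.ULT_true, 0.0, r)
        return r if r.ndim else float(r)


def th_for_topt(E: float, Eh: float, topt_C: float) -> float:
    """Half-inactivation temperature (K) placing the curve optimum at ``topt_C``.

    Inverts the closed-form optimum Topt = Eh*Th / (Eh + k*Th*ln(Eh/E - 1)).
    """
    if not Eh > E > 0:
        raise ValueError("require Eh > E > 0")
    topt_K = topt_C + CELSIUS_TO_KELVIN
    L = math.log(Eh / E - 1.0)
    denom = Eh - K_BOLTZ * topt_K * L
    if denom <= 0:
        raise ValueError("no valid Th for these E, Eh, Topt")
    return topt_K * Eh / denom


def ss_params_for(topt_C: float, hr_max: float, E: float, Eh: float = 4.0) -> SSParams:
    """Sharpe-Schoolfield parameters with a given optimum and peak rate."""
    Th = th_for_topt(E, Eh, topt_C)
    unit = SSParams(1.0, E, Eh, Th)
    return SSParams(hr_max / float(ss_rate(unit, topt_C)), E, Eh, Th)


def simulate_trace(
    traits: TrueTraits,
    ramp: RampProtocol,
    noise_sd: float = 0.2,
    seed: RngLike = 0,
    pulse_mV: float = 1.0,
    pulse_width_s: float = 0.15,
    interval_jitter: float = 0.05,
    meta: Optional[dict] = None,
) -> CardiacTrace:
    """Simulate a ramped heating trace for one individual.

    Beats form an inhomogeneous renewal process: each interval is
    ``60 / rate(T)`` seconds with 5% multiplicative jitter (heartbeats are
    quasi-regular, not Poisson). Each beat contributes a stereotyped Gaussian
    pulse of ~``pulse_width_s`` total width on a flat baseline with Gaussian
    sensor noise. Beats cease once body temperature reaches ``ULT_true``. The
    temperature channel follows the ramp exactly. Ground-truth beat times are
    kept in ``trace.meta['true_beat_times']``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    duration = ramp.duration_s
    n = int(round(duration * ramp.sample_hz)) + 1
    time = np.arange(n) / ramp.sample_hz
    temp = ramp.temp_at(time)

    beats = []
    r0 = float(traits.rate_bpm(ramp.start_C))
    t = rng.uniform(0.0, 60.0 / max(r0, 1e-6)) if r0 > 0 else duration
    while t < duration:
        T = float(ramp.temp_at(t))
        if T >= traits.ULT_true:
            break
        r = float(traits.rate_bpm(T))
        if r <= 1e-9:
            break
        beats.append(t)
        iv = 60.0 / r * (1.0 + interval_jitter * rng.standard_normal())
        t += max(iv, 0.05)
    beat_times = np.asarray(beats)

    signal = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    sd_samples = (pulse_width_s / 4.0) * ramp.sample_hz
    half = int(math.ceil(4 * sd_samples))
    for b in beat_times:
        c = int(round(b * ramp.sample_hz))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        idx = np.arange(lo, hi)
        signal[lo:hi] += pulse_mV * np.exp(-0.5 * ((idx - b * ramp.sample_hz) / sd_samples) ** 2)

    full_meta = dict(meta or {})
    full_meta["true_beat_times"] = beat_times
    full_meta["true_traits"] = traits
    return CardiacTrace(time, signal, temp, ramp.sample_hz, full_meta)


# ---------------------------------------------------------------------------
# Phylogenies and species traits
# ---------------------------------------------------------------------------

def yule_tree(
    n_species: int,
    seed: RngLike = 0,
    labels: Optional[Sequence[str]] = None,
    birth_rate: float = 1.0,
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with unit root-to-tip depth."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    if len(set(labels)) != n_species:
        raise ValueError("labels must be unique and match n_species")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    active = [(tree.seed_node.new_child(), 0.0), (tree.seed_node.new_child(), 0.0)]
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node, born = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - born
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(len(active))
    for lab, k in zip(labels, order):
        node, born = active[k]
        node.edge.length = t_end - born
        node.taxon = taxa.new_taxon(lab)
    for edge in tree.preorder_edge_iter():  # normalize depth to 1
        if edge.length is not None:
            edge.length /= t_end
    tree.seed_node.edge.length = None
    return tree


def simulate_tree_and_traits(
    n_species: int,
    habitat_split: float = 0.5,
    beta_habitat: float = 1.0,
    sigma2_bm: float = 1.0,
    lambda_true: float = 1.0,
    seed: RngLike = 0,
    intercept: float = 0.0,
    tree: Optional[dendropy.Tree] = None,
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Pure-birth tree plus one trait with a habitat effect and phylogenetic noise.

    Trait = intercept + beta_habitat * habitat + MVN(0, sigma2_bm * C_lambda),
    where C_lambda is the Brownian covariance with off-diagonals scaled by
    ``lambda_true``. Returns (tree, trait table, ground-truth dict). Pass a
    ``tree`` to reuse a fixed topology across replicates.
    """
    if n_species < 3:
        raise ValueError("PGLS needs at least 3 species")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must lie in [0, 1]")
    rng = _rng(seed)
    if tree is None:
        tree = yule_tree(n_species, rng)
    from .pgls import phylo_cov  # deferred: pgls does not import synthetic

    C, labels = phylo_cov(tree, lambda_true)
    n = len(labels)
    habitat = np.zeros(n, dtype=int)
    n_hab = int(round(habitat_split * n))
    habitat[rng.permutation(n)[:n_hab]] = 1
    mean = intercept + beta_habitat * habitat
    if sigma2_bm > 0:
        L = cholesky(sigma2_bm * C + 1e-12 * np.eye(n), lower=True)
        values = mean + L @ rng.standard_normal(n)
    else:
        values = mean.astype(float)
    table = pd.DataFrame({"species": labels, "habitat": habitat, "value": values})
    truth = {
        "beta_habitat": beta_habitat,
        "sigma2_bm": sigma2_bm,
        "lambda": lambda_true,
        "intercept": intercept,
    }
    return tree, table, truth


# ---------------------------------------------------------------------------
# Trait cohorts with a prescribed dispersion structure
# ---------------------------------------------------------------------------

TRAIT_NAMES = ["slope_gradient", "slope_curvature", "hr_max", "t_opt", "ult"]
TEMPERATURE_TRAITS = {"t_opt", "ult"}

#: Default between-individual coefficients of variation (%), per trait.
#: Temperature traits are dispersed on the Kelvin scale. The hierarchy —
#: the lethal limit far more canalized than the performance traits — is the
#: variability structure the cohort generator emulates.
DEFAULT_TRAIT_CV = {
    "ult": 0.955,
    "t_opt": 2.19,
    "hr_max": 12.6,
    "slope_gradient": 19.2,
    "slope_curvature": 91.1,
}

#: Default six-species study design: three rocky-shore and three mangrove
#: species, slope gradient (activation energy) lower in the mangrove lineage,
#: peak heart rates spanning ~108-151 bpm.
DEFAULT_SPECIES_MEANS = pd.DataFrame(
    [
        ("rocky_high", "rocky", 1.00, -0.30, 150.0, 41.0, 52.5),
        ("rocky_mid", "rocky", 0.90, -0.35, 130.0, 40.5, 52.0),
        ("rocky_low", "rocky", 0.80, -0.25, 115.0, 39.5, 51.5),
        ("mangrove_trunk", "mangrove", 0.65, -0.28, 135.0, 40.5, 52.0),
        ("mangrove_mud", "mangrove", 0.60, -0.22, 125.0, 40.0, 51.8),
        ("mangrove_fresh", "mangrove", 0.55, -0.30, 108.0, 39.3, 51.3),
    ],
    columns=["species", "habitat", "slope_gradient", "slope_curvature",
             "hr_max", "t_opt", "ult"],
)


def simulate_trait_cohort(
    n_individuals: int = 9,
    seed: RngLike = 0,
    species_means: Optional[pd.DataFrame] = None,
    trait_cv: Optional[dict] = None,
) -> pd.DataFrame:
    """Long-format trait table (species, habitat, individual, trait, value).

    Individual values are Gaussian around the species mean with a standard
    deviation set by the per-trait CV%; temperature traits are dispersed on
    the Kelvin scale (CV is defined on Kelvin for them).
    """
    if n_individuals < 2:
        raise ValueError("need >= 2 individuals per species")
    rng = _rng(seed)
    means = DEFAULT_SPECIES_MEANS if species_means is None else species_means
    cv = DEFAULT_TRAIT_CV if trait_cv is None else trait_cv
    rows = []
    for _, sp in means.iterrows():
        for ind in range(1, n_individuals + 1):
            for trait in TRAIT_NAMES:
                mu = float(sp[trait])
                scale_mu = mu + CELSIUS_TO_KELVIN if trait in TEMPERATURE_TRAITS else mu
                sd = cv[trait] / 100.0 * abs(scale_mu)
                rows.append((sp["species"], sp["habitat"], f"{sp['species']}_{ind:02d}",
                             trait, mu + sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["species", "habitat", "individual",
                                       "trait", "value"])
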