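"""End-to-end pipeline: simulate cohort -> per-individual traits -> comparisons.

Stages are independently re-runnable from their on-disk intermediates (trace
CSVs, trait TSV, Newick tree); every output embeds the config hash and seed
in commented header lines so runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cardiotrace as ct
from . import pgls as pg
from . import stats as st
from . import synthetic as syn
from . import tpc

log = logging.getLogger("ctpc")

TRAIT_COLUMNS = ["species", "habitat", "individual", "slope_gradient_eV",
                 "slope_curvature", "hr_max_bpm", "t_opt_C", "ult_C",
                 "fit_ok", "rss"]

#: trait-table column <-> analysis trait name
TRAIT_MAP = {
    "slope_gradient": "slope_gradient_eV",
    "slope_curvature": "slope_curvature",
    "hr_max": "hr_max_bpm",
    "t_opt": "t_opt_C",
    "ult": "ult_C",
}


class UserError(Exception):
    """Invalid configuration or input supplied by the caller."""


@dataclass
class SpeciesSpec:
    """Species-level mean trait values driving the trace generator."""

    name: str
    habitat: str
    slope_gradient: float  # activation energy E, eV
    hr_max: float  # bpm
    t_opt: float  # deg C
    ult: float  # deg C
    eh: float = 4.0  # deactivation energy, eV
    depression_fraction: float = 0.0  # share of individuals with a plateau


# Default study design: six species, slope gradient lower in the mangrove
# lineage, HRmax spanning ~108-150 bpm, a minority of individuals showing the
# low-temperature metabolic-depression plateau.
DEFAULT_SPECIES = [
    SpeciesSpec("rocky_high", "rocky", 1.00, 150.0, 41.0, 52.5,
                depression_fraction=0.11),
    SpeciesSpec("rocky_mid", "rocky", 0.90, 130.0, 40.5, 52.0,
                depression_fraction=0.33),
    SpeciesSpec("rocky_low", "rocky", 0.80, 115.0, 39.5, 51.5),
    SpeciesSpec("mangrove_trunk", "mangrove", 0.65, 135.0, 40.5, 52.0,
                depression_fraction=0.44),
    SpeciesSpec("mangrove_mud", "mangrove", 0.60, 125.0, 40.0, 51.8,
                depression_fraction=0.33),
    SpeciesSpec("mangrove_fresh", "mangrove", 0.55, 108.0, 39.3, 51.3),
]


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Serializable to/from YAML."""

    seed: int = 0
    n_individuals: int = 9
    species: list = field(default_factory=lambda: [dataclasses.replace(s)
                                                   for s in DEFAULT_SPECIES])
    # ramp protocol
    ramp_start_C: float = 30.0
    ramp_end_C: float = 65.0
    ramp_rate_C_per_min: float = 0.25
    sample_hz: float = 40.0
    # trace generation
    noise_sd_mV: float = 0.2
    pulse_mV: float = 1.0
    pulse_width_s: float = 0.15
    # individual-level dispersion
    sd_gradient_frac: float = 0.192
    sd_hrmax_frac: float = 0.126
    sd_topt_C: float = 1.5
    sd_ult_C: float = 1.0
    depression_cap_bpm: float = 60.0
    depression_onset_C: float = 40.0
    # detection / fitting
    smooth_window_s: float = 0.15  # 0 = analyse the raw trace
    refractory_s: float = 0.25
    min_prominence_mV: Optional[float] = None  # None = 4 x MAD per trace
    window_s: float = 60.0
    step_s: float = 30.0
    hr_floor_bpm: float = 5.0
    sustain_s: float = 120.0
    n_starts: int = 20
    # comparisons
    models: list = field(default_factory=lambda: list(pg.MODELS))
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.species = [s if isinstance(s, SpeciesSpec) else SpeciesSpec(**s)
                        for s in self.species]
        for name in ("refractory_s", "window_s", "step_s", "hr_floor_bpm",
                     "sustain_s", "sample_hz", "ramp_rate_C_per_min"):
            if not getattr(self, name) > 0:
                raise UserError(f"{name} must be positive")

    @property
    def ramp(self) -> syn.RampProtocol:
        return syn.RampProtocol(self.ramp_start_C, self.ramp_end_C,
                                self.ramp_rate_C_per_min, self.sample_hz)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise UserError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise UserError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def header_lines(self) -> list:
        return [f"config_hash={self.config_hash}", f"seed={self.seed}"]


def _write_table(df: pd.DataFrame, path: Path, header_lines, sep="\t") -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def _read_table(path: Path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# Stage 1: simulate
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir, overwrite: bool = False) -> pd.DataFrame:
    """Write trace CSVs, ground-truth manifest and species tree; return the manifest."""
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    if tracedir.exists() and any(tracedir.iterdir()) and not overwrite:
        raise UserError(f"{tracedir} already contains traces (use overwrite)")
    tracedir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    header = config.header_lines()

    labels = [s.name for s in config.species]
    tree = syn.yule_tree(len(labels), int(rng.integers(2 ** 31)), labels=labels)
    (outdir / "tree.nwk").write_text(pg.write_newick(tree) + "\n")

    rows = []
    for sp in config.species:
        for ind in range(1, config.n_individuals + 1):
            E = max(sp.slope_gradient * (1 + config.sd_gradient_frac
                                         * rng.standard_normal()), 0.05)
            t_opt = sp.t_opt + config.sd_topt_C * rng.standard_normal()
            hr = max(sp.hr_max * (1 + config.sd_hrmax_frac
                                  * rng.standard_normal()), 10.0)
            ult = sp.ult + config.sd_ult_C * rng.standard_normal()
            ult = max(ult, t_opt + 2.0)  # lethal limit above the optimum
            cap = (config.depression_cap_bpm
                   if rng.uniform() < sp.depression_fraction else None)
            base = syn.ss_params_for(t_opt, hr, E, sp.eh)
            traits = syn.TrueTraits(base.r_tref, E, sp.eh, base.Th, ult,
                                    depression_cap=cap,
                                    depression_onset_C=config.depression_onset_C)
            ind_id = f"{sp.name}_{ind:02d}"
            trace = syn.simulate_trace(
                traits, config.ramp, noise_sd=config.noise_sd_mV,
                seed=int(rng.integers(2 ** 31)), pulse_mV=config.pulse_mV,
                pulse_width_s=config.pulse_width_s,
                meta={"species": sp.name, "habitat": sp.habitat,
                      "individual": ind_id},
            )
            trace.to_csv(tracedir / f"{ind_id}.csv",
                         header_lines=header + [f"species={sp.name}",
                                                f"habitat={sp.habitat}",
                                                f"individual={ind_id}"])
            rows.append({
                "species": sp.name, "habitat": sp.habitat, "individual": ind_id,
                "r_tref_bpm": traits.r_tref, "E_eV": traits.E,
                "Eh_eV": traits.Eh, "Th_K": traits.Th,
                "ult_true_C": traits.ULT_true,
                "t_opt_true_C": tpc.topt_closed_form(traits.ss_params),
                "hr_max_true_bpm": float(tpc.ss_rate(
                    traits.ss_params, tpc.topt_closed_form(traits.ss_params))),
                "depression_cap_bpm": "" if cap is None else cap,
            })
    manifest = pd.DataFrame(rows)
    _write_table(manifest, outdir / "truth_traits.tsv", header)
    config.to_yaml(outdir / "config.yaml")
    log.info("simulated %d traces into %s", len(manifest), tracedir)
    return manifest


# ---------------------------------------------------------------------------
# Stage 2: per-individual traits
# ---------------------------------------------------------------------------

def process_trace(trace: ct.CardiacTrace, config: RunConfig,
                  fit_seed: int = 0) -> tpc.CardiacTraits:
    """Full single-individual chain: smooth? -> beats -> rate windows -> flatline -> fit."""
    if config.smooth_window_s > 0:
        # never below the 3-sample kernel minimum at low sample rates
        window = max(config.smooth_window_s, 3.0 / trace.sample_hz)
        trace = ct.bartlett_smooth(trace, window)
    beats = ct.detect_beats(trace, config.min_prominence_mV, config.refractory_s)
    series = ct.hr_series(beats, trace, config.window_s, config.step_s)
    flat = ct.detect_flatline(series, config.hr_floor_bpm, config.sustain_s)
    fit = tpc.fit_ss(series, n_starts=config.n_starts, seed=fit_seed,
                     flatline=flat)
    return tpc.extract_traits(fit, series, flat)


def run_traits(config: RunConfig, workdir) -> pd.DataFrame:
    """Fit every trace in ``workdir/traces``; write and return the trait table."""
    workdir = Path(workdir)
    tracedir = workdir / "traces"
    files = sorted(tracedir.glob("*.csv")) if tracedir.is_dir() else []
    if not files:
        raise UserError(f"no trace files found under {tracedir}")
    rows = []
    for f in files:
        trace = ct.CardiacTrace.from_csv(f)
        ind_id = f.stem
        species, _, ind = ind_id.rpartition("_")
        fit_seed = (config.seed + zlib.crc32(f.name.encode())) % (2 ** 31)
        try:
            traits = process_trace(trace, config, fit_seed)
        except ct.TraceError as exc:
            log.warning("trace %s failed: %s", f.name, exc)
            traits = tpc.CardiacTraits(None, None, None, None, None, False)
        log.info("%s: fit_ok=%s rss=%.3g ult=%s", ind_id, traits.fit_ok,
                 traits.rss, traits.ult)
        rows.append({
            "species": species, "habitat": "", "individual": ind_id,
            "slope_gradient_eV": traits.slope_gradient,
            "slope_curvature": traits.slope_curvature,
            "hr_max_bpm": traits.hr_max, "t_opt_C": traits.t_opt,
            "ult_C": traits.ult, "fit_ok": traits.fit_ok, "rss": traits.rss,
        })
    table = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    # habitat labels come from the manifest when present
    manifest_path = workdir / "truth_traits.tsv"
    if manifest_path.exists():
        manifest = _read_table(manifest_path)
        table["habitat"] = table["individual"].map(
            manifest.set_index("individual")["habitat"])
    _write_table(table, workdir / "traits.tsv", config.header_lines())
    return table


def traits_long(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-individual trait table -> long (species, habitat, individual, trait, value)."""
    sub = table[table["fit_ok"].astype(bool)]
    out = []
    for trait, col in TRAIT_MAP.items():
        part = sub[["species", "habitat", "individual", col]].rename(
            columns={col: "value"})
        part.insert(3, "trait", trait)
        out.append(part.dropna(subset=["value"]))
    return pd.concat(out, ignore_index=True)


def species_means(long_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic species means (temperatures averaged in Celsius), wide format."""
    wide = (long_table.pivot_table(index=["species", "habitat"], columns="trait",
                                   values="value", aggfunc="mean")
            .reset_index())
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# Stage 3: comparisons
# ---------------------------------------------------------------------------

def run_compare(config: RunConfig, workdir) -> dict:
    """PGLS model comparison, habitat-specific species tests, CV% summary."""
    workdir = Path(workdir)
    traits_path = workdir / "traits.tsv"
    tree_path = workdir / "tree.nwk"
    if not traits_path.exists():
        raise UserError(f"missing trait table {traits_path}")
    if not tree_path.exists():
        raise UserError(f"missing tree {tree_path}")
    table = _read_table(traits_path)
    tree = pg.read_newick(tree_path.read_text())
    long = traits_long(table)
    means = species_means(long)

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(means["species"]) - tips)
    if missing:
        raise UserError(f"species absent from the tree: {missing}")

    traits = [t for t in TRAIT_MAP if t in means.columns]
    pgls_out = pg.pgls_table(means, tree, traits, models=config.models)

    # species under-replicated for a trait (failed fits, absent flatlines)
    # cannot enter the within-habitat tests or CV summaries
    counts = long.groupby(["trait", "species"])["value"].transform("size")
    long = long[counts >= 2]

    stat_rows, tukey_rows = [], []
    for habitat, hsub in long.groupby("habitat"):
        for trait, tsub in hsub.groupby("trait"):
            if tsub["species"].nunique() < 2:
                log.warning("skipping %s/%s: fewer than 2 species with "
                            ">= 2 individuals", habitat, trait)
                continue
            full = st.fit_lm(tsub["value"], tsub["species"], response=trait)
            test = st.lrt(full, st.intercept_only(tsub["value"], response=trait))
            tk = st.tukey_hsd(full, alpha=config.alpha)
            letters = " ".join(f"{lv}:{tk.letters[lv]}" for lv in sorted(tk.letters))
            stat_rows.append({"habitat": habitat, "trait": trait,
                              "chi2": test.chi2, "df": test.df, "p": test.p,
                              "letters": letters})
            pt = tk.table.assign(habitat=habitat, trait=trait)
            tukey_rows.append(pt)
    stats_out = pd.DataFrame(stat_rows)
    tukey_out = pd.concat(tukey_rows, ignore_index=True)
    cv_out = st.cv_table(long, traits)

    header = config.header_lines()
    _write_table(pgls_out, workdir / "pgls.tsv", header)
    _write_table(stats_out, workdir / "habitat_stats.tsv", header)
    _write_table(tukey_out, workdir / "tukey.tsv", header)
    _write_table(cv_out, workdir / "cv_summary.tsv", header)
    return {"pgls": pgls_out, "habitat_stats": stats_out,
            "tukey": tukey_out, "cv": cv_out}


def run_all(config: RunConfig, workdir, overwrite: bool = False) -> dict:
    run_simulate(config, workdir, overwrite=overwrite)
    run_traits(config, workdir)
    return run_compare(config, workdir)
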