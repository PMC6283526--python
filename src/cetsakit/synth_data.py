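"""Synthetic CETSA experiments with ground-truth binder labels.

The generator emulates the measurement chain of a 10-plex thermal shift
experiment well enough to exercise every pipeline stage:

* protein melting as a logistic loss of soluble fraction in temperature,
  with protein-specific Tm (default N(52, 4) degC, the median soluble-
  proteome melting temperature), transition slope and residual plateau;
* ligand binding as single-site occupancy, dose/(dose + Kd), shifting Tm by
  up to ``max_tm_shift`` degC at saturation;
* TMT reporter abundances as base abundance x soluble fraction x
  multiplicative lognormal noise (reporter ratios are ratio-scale); melt
  runs draw noise for every channel, while isothermal designs draw it on
  the dose/time-response ratio (the reference abundance stays exact);
* per-run, per-channel missingness and optional 37 degC abundance changes
  for the expression-control stage.

The melt generator works in linear temperature by default while the
analysis fits a log-temperature LL.4 model -- a deliberate, realistic model
mismatch.  Setting ``melt_in_log_temperature=True`` makes the generated
curves exactly LL.4-representable, which turns noiseless parameter recovery
into a strict oracle.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .quant_io import ChannelMap, ColumnRoles, ProteinQuant, write_quant_table

MELT_TEMPERATURES = tuple(range(37, 65, 3))           # 37..64 degC, 3 degC steps
DEFAULT_DOSE_LADDER = tuple(25000.0 / 4 ** k for k in range(9, -1, -1))
DEFAULT_TIME_GRID = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated CETSA experiment.

    Defaults mirror the published designs: 10-point melts at 37-64 degC,
    a 10-dose 4-fold ITDR ladder topping at 25 mM, Tm ~ N(52, 4) degC, and
    lognormal reporter noise sigma = 0.08 (the resulting 2.5 * MAD baseline
    band spans roughly +/- 0.3 fold change).
    """

    n_proteins: int
    seed: int
    n_binders: int = 0
    tm_mean: float = 52.0
    tm_sd: float = 4.0
    slope_range: Tuple[float, float] = (0.4, 1.2)        # 1/degC
    plateau_range: Tuple[float, float] = (0.0, 0.3)
    noise_sigma: float = 0.08
    kd_range: Tuple[float, float] = (0.4, 400.0)          # uM, doses 2..7 of the ladder
    max_tm_shift: float = 4.0                             # degC at full occupancy
    dose_ladder: Tuple[float, ...] = DEFAULT_DOSE_LADDER  # uM, ascending
    time_grid: Tuple[float, ...] = DEFAULT_TIME_GRID      # minutes
    missing_rate: float = 0.0
    abundance_change_rate: float = 0.0
    min_binder_effect: float = 1.5    # required noiseless full-occupancy FC
    n_replicates: int = 2
    melt_in_log_temperature: bool = False
    treatment: str = "compound"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("SimConfig.seed is mandatory")
        for name, rng in (("slope_range", self.slope_range),
                          ("plateau_range", self.plateau_range),
                          ("kd_range", self.kd_range)):
            if not rng[0] < rng[1]:
                raise ConfigurationError(f"{name} must be non-degenerate")
        if not (0 <= self.missing_rate < 1) or not (0 <= self.abundance_change_rate < 1):
            raise ConfigurationError("rates must lie in [0, 1)")
        if len(self.dose_ladder) != 10 or len(self.time_grid) != 10:
            raise ConfigurationError("dose ladder and time grid need 10 points")


@dataclass
class SimulatedExperiment:
    """Quantification tables, channel maps and ground truth of one simulation."""

    runs: Dict[str, List[ProteinQuant]]
    channel_maps: Dict[str, ChannelMap]
    truth: pd.DataFrame
    config: SimConfig
    control_37c: Optional[pd.DataFrame] = None


def soluble_fraction(tm, slope, plateau, T):
    """Remaining soluble fraction after a heat pulse at temperature T.

    Logistic in (linear) temperature: plateau + (1 - plateau)/(1 + exp(slope*(T - tm))).
    At T = tm the value is (1 + plateau)/2; far below tm it approaches 1.
    """
    return plateau + (1.0 - plateau) / (1.0 + np.exp(slope * (np.asarray(T, float) - tm)))


def soluble_fraction_logt(tm, slope, plateau, T):
    """Log-temperature variant (exactly LL.4-representable fold changes).

    The slope is rescaled by a nominal 40 degC so the transition width is
    comparable to the linear-temperature model while the log-slope stays
    inside the fitter's working range."""
    b = slope * 40.0
    return plateau + (1.0 - plateau) / (1.0 + np.exp(b * (np.log(np.asarray(T, float)) - np.log(tm))))


def dosed_tm(tm0, dose, kd, max_shift):
    """Apparent Tm under single-site occupancy stabilization.

    tm0 + max_shift * dose/(dose + kd); zero dose leaves tm0 unchanged.
    """
    dose = np.asarray(dose, dtype=float)
    return tm0 + max_shift * dose / (dose + kd)


def uptake_occupancy(t, halftime):
    """Intracellular occupancy rising as 1 - exp(-t ln2 / halftime)."""
    return 1.0 - np.exp(-np.asarray(t, float) * np.log(2.0) / halftime)


# ---------------------------------------------------------------------------


def _draw_proteome(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_proteins
    tm0 = rng.normal(cfg.tm_mean, cfg.tm_sd, size=n)
    slope = rng.uniform(*cfg.slope_range, size=n)
    plateau = rng.uniform(*cfg.plateau_range, size=n)
    base = rng.lognormal(mean=np.log(1e5), sigma=1.0, size=n)
    psm = 1 + rng.poisson(6.0, size=n)
    peptides = 1 + rng.binomial(psm - 1, 0.6)
    return pd.DataFrame({
        "protein_id": [f"P{i:05d}" for i in range(n)],
        "tm0": tm0, "slope": slope, "plateau": plateau,
        "base_abundance": base, "psm_count": psm, "unique_peptides": peptides,
    })


def _pick_binders(cfg: SimConfig, rng: np.random.Generator,
                  prot: pd.DataFrame, eligible: np.ndarray) -> np.ndarray:
    """Deterministically pick binder indices among eligible proteins.

    A spike-in set is only meaningful inside the assay's dynamic range, so
    eligibility (computed by the caller) restricts to proteins whose
    programmed effect is observable and that carry >= 3 PSMs.
    """
    if cfg.n_binders == 0:
        return np.empty(0, dtype=int)
    idx = np.flatnonzero(eligible)
    if idx.size < cfg.n_binders:
        raise DataError(
            f"only {idx.size} proteins eligible as binders, need {cfg.n_binders}; "
            "widen the simulation or lower n_binders")
    return np.sort(rng.choice(idx, size=cfg.n_binders, replace=False))


def _records(prot: pd.DataFrame, abundances: np.ndarray, run_id: str) -> List[ProteinQuant]:
    return [
        ProteinQuant(
            protein_id=pid, description=f"synthetic protein {pid}",
            abundances=abundances[i], psm_count=int(psm),
            unique_peptides=int(pep), run_id=run_id,
        )
        for i, (pid, psm, pep) in enumerate(
            zip(prot["protein_id"], prot["psm_count"], prot["unique_peptides"]))
    ]


def _apply_noise_and_missing(values: np.ndarray, cfg: SimConfig,
                             rng: np.random.Generator,
                             ref_index: Optional[int] = None) -> np.ndarray:
    """Multiplicative lognormal noise + per-channel missingness.

    For isothermal designs (``ref_index`` given) the noise acts on the
    dose/time-response ratio, so the reference channel abundance stays
    noise-free; melt designs draw noise for every channel.
    """
    eps = rng.standard_normal(values.shape)
    if ref_index is not None:
        eps[:, ref_index] = 0.0
    noisy = values * np.exp(cfg.noise_sigma * eps)
    if cfg.missing_rate > 0:
        noisy = noisy.copy()
        noisy[rng.random(values.shape) < cfg.missing_rate] = np.nan
    return noisy


def _melt_soluble(cfg: SimConfig, tm, slope, plateau, T):
    f = soluble_fraction_logt if cfg.melt_in_log_temperature else soluble_fraction
    return f(tm, slope, plateau, T)


def simulate_melt_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Duplicate control + duplicate treatment melt runs (37-64 degC).

    Binders melt at tm0 + max_tm_shift in the treatment runs (a saturating
    treatment dose); binder labels are restricted to proteins with >= 3 PSMs
    and Tm inside [tm_mean - 1.5 sd, tm_mean + 1 sd] so the programmed shift
    falls within the sampled temperature window.
    """
    rng = np.random.default_rng(cfg.seed)
    prot = _draw_proteome(cfg, rng)
    temps = np.array(MELT_TEMPERATURES, dtype=float)

    eligible = ((prot["psm_count"].to_numpy() >= 3)
                & (prot["tm0"].to_numpy() >= cfg.tm_mean - 1.5 * cfg.tm_sd)
                & (prot["tm0"].to_numpy() <= cfg.tm_mean + 1.0 * cfg.tm_sd))
    binders = _pick_binders(cfg, rng, prot, eligible)
    is_binder = np.zeros(cfg.n_proteins, dtype=bool)
    is_binder[binders] = True
    shift = np.where(is_binder, cfg.max_tm_shift, 0.0)

    tm0 = prot["tm0"].to_numpy()[:, None]
    slope = prot["slope"].to_numpy()[:, None]
    plateau = prot["plateau"].to_numpy()[:, None]
    base = prot["base_abundance"].to_numpy()[:, None]

    runs: Dict[str, List[ProteinQuant]] = {}
    channel_maps: Dict[str, ChannelMap] = {}
    labels = [f"T{int(t)}" for t in temps]
    for treatment, tm_eff in (("vehicle", tm0),
                              (cfg.treatment, tm0 + shift[:, None])):
        for rep in range(1, cfg.n_replicates + 1):
            run_id = f"melt_{treatment}_r{rep}"
            clean = base * _melt_soluble(cfg, tm_eff, slope, plateau, temps[None, :])
            ab = _apply_noise_and_missing(clean, cfg, rng)
            runs[run_id] = _records(prot, ab, run_id)
            channel_maps[run_id] = ChannelMap(
                run_id=run_id, treatment=treatment, replicate=rep,
                channel_labels=labels, x_values=tuple(temps),
                x_kind="temperature", reference_index=0)

    truth = prot.copy()
    truth["is_binder"] = is_binder
    truth["kd"] = np.nan
    truth["true_tm_shift_at_top_dose"] = shift
    truth["abundance_factor"] = 1.0
    return SimulatedExperiment(runs=runs, channel_maps=channel_maps,
                               truth=truth, config=cfg)


def _itdr_eligibility(cfg: SimConfig, prot: pd.DataFrame, isotherm: float,
                      kd: Optional[np.ndarray] = None) -> np.ndarray:
    """Proteins whose observable dose-response plateau at the isotherm
    reaches min_binder_effect, with enough PSM evidence.

    The observable (apparent) plateau is the fold change of the top dose
    relative to the lowest-dose reference, which for small Kd is already
    partly occupied; with ``kd=None`` full occupancy at the top and none at
    the reference is assumed (saturating time-course designs).
    """
    tm0 = prot["tm0"].to_numpy()
    slope = prot["slope"].to_numpy()
    plateau = prot["plateau"].to_numpy()
    if kd is None:
        occ_ref, occ_top = 0.0, 1.0
    else:
        doses = np.asarray(cfg.dose_ladder, dtype=float)
        occ_ref = doses[0] / (doses[0] + kd)
        occ_top = doses[-1] / (doses[-1] + kd)
    fc_app = (soluble_fraction(tm0 + cfg.max_tm_shift * occ_top, slope, plateau, isotherm)
              / soluble_fraction(tm0 + cfg.max_tm_shift * occ_ref, slope, plateau, isotherm))
    return (prot["psm_count"].to_numpy() >= 3) & (fc_app >= cfg.min_binder_effect)


def simulate_itdr_experiment(cfg: SimConfig, isotherm: float = 52.0) -> SimulatedExperiment:
    """Technical-replicate ITDR runs at one isotherm (default 52 degC).

    Binders get Kd log-uniform over ``kd_range``; their apparent Tm at dose
    d is tm0 + max_tm_shift * d/(d + Kd).  Also emits a 37 degC no-heat
    control table in which an ``abundance_change_rate`` fraction of
    non-binders change expression (lognormal(0, 0.15) factor) to exercise
    the abundance-control stage.
    """
    rng = np.random.default_rng(cfg.seed)
    prot = _draw_proteome(cfg, rng)
    doses = np.array(cfg.dose_ladder, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ConfigurationError("dose_ladder must be strictly ascending")

    # Latent affinity per protein; only binders' values become real.
    lo, hi = np.log(cfg.kd_range[0]), np.log(cfg.kd_range[1])
    kd_latent = np.exp(rng.uniform(lo, hi, size=cfg.n_proteins))
    binders = _pick_binders(
        cfg, rng, prot, _itdr_eligibility(cfg, prot, isotherm, kd=kd_latent))
    n = cfg.n_proteins
    is_binder = np.zeros(n, dtype=bool)
    is_binder[binders] = True
    kd = np.where(is_binder, kd_latent, np.nan)

    tm0 = prot["tm0"].to_numpy()
    slope = prot["slope"].to_numpy()[:, None]
    plateau = prot["plateau"].to_numpy()[:, None]
    base = prot["base_abundance"].to_numpy()[:, None]

    tm_d = np.repeat(tm0[:, None], len(doses), axis=1)
    if binders.size:
        tm_d[binders] = dosed_tm(tm0[binders, None], doses[None, :],
                                 kd[binders, None], cfg.max_tm_shift)
    clean = base * soluble_fraction(tm_d, slope, plateau, isotherm)

    runs: Dict[str, List[ProteinQuant]] = {}
    channel_maps: Dict[str, ChannelMap] = {}
    labels = [f"D{k + 1}" for k in range(len(doses))]
    for rep in range(1, cfg.n_replicates + 1):
        run_id = f"itdr_{cfg.treatment}_r{rep}"
        ab = _apply_noise_and_missing(clean, cfg, rng, ref_index=0)
        runs[run_id] = _records(prot, ab, run_id)
        channel_maps[run_id] = ChannelMap(
            run_id=run_id, treatment=cfg.treatment, replicate=rep,
            channel_labels=labels, x_values=tuple(doses),
            x_kind="concentration", reference_index=0)

    # 37 degC expression control (no heat pulse, so no stability signal).
    factor = np.ones(n)
    if cfg.abundance_change_rate > 0:
        changed = (~is_binder) & (rng.random(n) < cfg.abundance_change_rate)
        factor[changed] = rng.lognormal(0.0, 0.15, size=int(changed.sum()))
    sigma = cfg.noise_sigma
    control = base[:, 0] * np.exp(sigma * rng.standard_normal(n))
    treated = base[:, 0] * factor * np.exp(sigma * rng.standard_normal(n))
    control_37c = pd.DataFrame({
        "protein_id": prot["protein_id"],
        "control_abundance": control,
        "treated_abundance": treated,
    })

    truth = prot.copy()
    truth["is_binder"] = is_binder
    truth["kd"] = kd
    occ_top = doses[-1] / (doses[-1] + kd)
    truth["true_tm_shift_at_top_dose"] = np.where(
        is_binder, cfg.max_tm_shift * np.where(np.isfinite(occ_top), occ_top, 0.0), 0.0)
    truth["abundance_factor"] = factor
    return SimulatedExperiment(runs=runs, channel_maps=channel_maps, truth=truth,
                               config=cfg, control_37c=control_37c)


def simulate_ittr_experiment(cfg: SimConfig, uptake_halftime: float = 20.0,
                             isotherm: float = 52.0) -> SimulatedExperiment:
    """Isothermal time-response runs: occupancy rises with compound uptake.

    The compound is at a saturating dose; a binder's shift at time t is
    max_tm_shift * (1 - exp(-t ln2 / uptake_halftime)).  t = 0 (reference)
    means no shift; t = uptake_halftime gives half-maximal occupancy.
    """
    rng = np.random.default_rng(cfg.seed)
    prot = _draw_proteome(cfg, rng)
    times = np.array(cfg.time_grid, dtype=float)

    binders = _pick_binders(cfg, rng, prot, _itdr_eligibility(cfg, prot, isotherm))
    n = cfg.n_proteins
    is_binder = np.zeros(n, dtype=bool)
    is_binder[binders] = True

    occ = uptake_occupancy(times, uptake_halftime)
    tm0 = prot["tm0"].to_numpy()
    shift = np.where(is_binder[:, None], cfg.max_tm_shift * occ[None, :], 0.0)
    clean = (prot["base_abundance"].to_numpy()[:, None]
             * soluble_fraction(tm0[:, None] + shift,
                                prot["slope"].to_numpy()[:, None],
                                prot["plateau"].to_numpy()[:, None], isotherm))

    runs: Dict[str, List[ProteinQuant]] = {}
    channel_maps: Dict[str, ChannelMap] = {}
    labels = [f"t{int(t)}" for t in times]
    for rep in range(1, cfg.n_replicates + 1):
        run_id = f"ittr_{cfg.treatment}_r{rep}"
        ab = _apply_noise_and_missing(clean, cfg, rng, ref_index=0)
        runs[run_id] = _records(prot, ab, run_id)
        channel_maps[run_id] = ChannelMap(
            run_id=run_id, treatment=cfg.treatment, replicate=rep,
            channel_labels=labels, x_values=tuple(times),
            x_kind="time", reference_index=0)

    truth = prot.copy()
    truth["is_binder"] = is_binder
    truth["kd"] = np.nan
    truth["true_tm_shift_at_top_dose"] = np.where(
        is_binder, cfg.max_tm_shift * occ[-1], 0.0)
    truth["abundance_factor"] = 1.0
    truth["uptake_halftime"] = np.where(is_binder, uptake_halftime, np.nan)
    return SimulatedExperiment(runs=runs, channel_maps=channel_maps,
                               truth=truth, config=cfg)


def write_experiment(exp: SimulatedExperiment, out_dir,
                     columns: ColumnRoles = ColumnRoles()) -> Path:
    """Write TSV quantification tables, truth CSV and a ready-to-run
    pipeline config YAML; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_entries = []
    for run_id, records in exp.runs.items():
        path = out / f"{run_id}.tsv"
        write_quant_table(records, path, fmt="tsv", columns=columns)
        cm = exp.channel_maps[run_id]
        run_entries.append({"run_id": run_id, "path": str(path.name),
                            "treatment": cm.treatment, "replicate": cm.replicate})
    exp.truth.to_csv(out / "truth.csv", index=False)
    if exp.control_37c is not None:
        exp.control_37c.to_csv(out / "control_37c.csv", index=False)

    cm0 = next(iter(exp.channel_maps.values()))
    kind = {"temperature": "melt", "concentration": "itdr", "time": "ittr"}[cm0.x_kind]
    config = {
        "experiment": kind,
        "seed": exp.config.seed,
        "runs": run_entries,
        "channel_map": {
            "x_kind": cm0.x_kind,
            "x_values": [float(v) for v in cm0.x_values],
            "channel_labels": list(cm0.channel_labels),
            "reference_index": cm0.reference_index,
        },
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
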