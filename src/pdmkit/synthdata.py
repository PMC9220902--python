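"""Synthetic PDM cohort generation with known ground truth.

No patient-level RPPA, plate-reader or imaging data from microtumor screens
are publicly deposited, so the pipeline ships a generator that emulates the
statistical structure of every input it consumes:

* 116-protein NFI matrices over a small cohort of PDM models, with
  pathway-structured group effects planted in responder models and a small
  fraction of proteins forced to blank level to exercise the quality filter;
* long-format cytotoxicity plate tables (DMSO-normalized RFU readouts at
  3 doses x 3 time points, 3-8 replicates) with multiplicative outliers;
* treated-vs-vehicle RPPA pairs at 0.5/4/72 h with planted per-pathway
  log2 trajectories;
* mask-level fluorescence sums for TIL-mediated killing assays with planted
  per-arm dead:viable ratios.

Every planted effect is recorded in a :class:`SimTruth` so downstream
recovery can be scored.  All four generators are deterministic for a fixed
seed; each draws from its own substream of the global seed so components
are reproducible independently.

Noise is log-normal on the linear fluorescence scales (normal on log2),
matching the ratio-based analysis scale of the pipeline.  RPPA samples are
simulated as the mean of two technical replicates, the standard acquisition
scheme for NFI readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .killing import KillingRecord
from .rppa import NFIMatrix, PATHWAY_PANELS, RAW_LINEAR

#: Default panel sizes over the eight pathway panels (sum = 116 proteins).
DEFAULT_PATHWAY_SIZES = {
    "cell cycle": 20,
    "DNA damage response": 15,
    "apoptosis": 15,
    "chromatin regulation": 12,
    "MAPK/RTK": 18,
    "PI3K/AKT-mTOR-Wnt-NFkB": 20,
    "tumor/stem cell markers": 10,
    "other": 6,
}

#: Planted treated/vehicle log2 trajectories at 0.5 / 4 / 72 h.  The default
#: mimics a platinum response: early stress-pathway induction (mTOR axis up
#: at 0.5-4 h), late collapse of cell-cycle and MAPK signaling at 72 h, and
#: progressive apoptosis induction.
DEFAULT_TR_TRAJECTORIES = {
    "cell cycle": (-0.6, 0.8, -1.5),
    "apoptosis": (0.0, 0.7, 1.2),
    "PI3K/AKT-mTOR-Wnt-NFkB": (0.7, 0.9, -1.2),
    "MAPK/RTK": (0.0, 0.3, -1.0),
}

#: Planted per-arm dead:viable PDM ratios for the co-culture killing assay.
DEFAULT_KILLING_ARMS = {
    "PDM": 0.05,
    "PDM+TIL": 0.20,
    "PDM+TIL+IgG4": 0.20,
    "PDM+TIL+CPI": 0.40,
}

_SUBSTREAMS = {"rppa": 0, "plate": 1, "tr": 2, "killing": 3}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the shape of a small ovarian-cancer PDM study: 7 models
    of which 4 respond to the drug of interest, 116 proteins over eight
    pathway panels, plates with 3 doses x 24/48/72 h and 6 replicates,
    treatment/vehicle pairs at 0.5/4/72 h, and 9 imaged PDM per co-culture
    arm (3 PDM per well, triplicate wells).
    """

    seed: int = 0
    n_models: int = 7
    n_proteins: int = 116
    pathway_sizes: dict = field(default_factory=lambda: dict(DEFAULT_PATHWAY_SIZES))
    responder_models: tuple | None = None  # default: first 4 model ids
    effect_log2: dict = field(default_factory=lambda: {"cell cycle": 0.8})
    noise_sd_log2: float = 0.25
    baseline_sd_log2: float = 1.0
    n_technical_replicates: int = 2
    blank_fraction: float = 0.05
    # plate assay
    drugs: tuple = ("carboplatin",)
    plate_doses: tuple = (75.0, 150.0, 300.0)  # uM
    plate_times: tuple = (24, 48, 72)  # h
    n_replicates: int = 6
    plate_base_rfu: float = 1000.0
    plate_noise_sd_log2: float = 0.1
    plate_effect_fc: dict | None = None  # model -> planted FC; default 2.0 resp / 1.0
    outlier_rate: float = 0.02
    outlier_magnitude: float = 5.0
    # treated/vehicle time-course pairs
    tr_times: tuple = (0.5, 4.0, 72.0)  # h
    tr_trajectories: dict = field(default_factory=lambda: dict(DEFAULT_TR_TRAJECTORIES))
    tr_noise_sd_log2: float = 0.2
    tr_model: str = "OvCa_04"
    # co-culture killing assay
    killing_arms: dict = field(default_factory=lambda: dict(DEFAULT_KILLING_ARMS))
    killing_noise_sd: float = 0.05
    n_pdm_per_well: int = 3
    n_wells: int = 3

    def __post_init__(self) -> None:
        if sum(self.pathway_sizes.values()) != self.n_proteins:
            raise ConfigError(
                f"pathway_sizes sums to {sum(self.pathway_sizes.values())}, "
                f"expected n_proteins={self.n_proteins}"
            )
        unknown = set(self.pathway_sizes) - set(PATHWAY_PANELS)
        if unknown:
            raise ConfigError(f"unknown pathway panels: {sorted(unknown)}")
        if not 3 <= self.n_replicates <= 8:
            raise ConfigError("n_replicates must lie in [3, 8]")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ConfigError("outlier_rate must lie in [0, 1)")
        for name, value in (
            ("noise_sd_log2", self.noise_sd_log2),
            ("baseline_sd_log2", self.baseline_sd_log2),
            ("plate_noise_sd_log2", self.plate_noise_sd_log2),
            ("tr_noise_sd_log2", self.tr_noise_sd_log2),
            ("killing_noise_sd", self.killing_noise_sd),
            ("outlier_magnitude", self.outlier_magnitude),
        ):
            if not math.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be finite and non-negative")
        for pw, eff in self.effect_log2.items():
            if not math.isfinite(eff):
                raise ConfigError(f"effect_log2[{pw!r}] is not finite")
        if not 0.0 <= self.blank_fraction < 1.0:
            raise ConfigError("blank_fraction must lie in [0, 1)")
        if self.responder_models is None:
            n_resp = min(4, max(1, self.n_models - 1))
            self.responder_models = tuple(self.model_ids[:n_resp])
        else:
            self.responder_models = tuple(self.responder_models)
            missing = set(self.responder_models) - set(self.model_ids)
            if missing:
                raise ConfigError(f"responder_models not in cohort: {sorted(missing)}")

    @property
    def model_ids(self) -> list:
        return [f"OvCa_{i + 1:02d}" for i in range(self.n_models)]

    @property
    def protein_ids(self) -> list:
        return [f"P{i + 1:03d}" for i in range(self.n_proteins)]

    def pathway_assignment(self) -> pd.Series:
        """Block assignment of proteins to panels, in panel order."""
        labels: list = []
        for panel in PATHWAY_PANELS:
            labels.extend([panel] * self.pathway_sizes.get(panel, 0))
        return pd.Series(labels, index=self.protein_ids, name="pathway")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_SUBSTREAMS[component],))
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort component."""

    responder_models: tuple = ()
    differential_proteins: list = field(default_factory=list)
    blank_proteins: list = field(default_factory=list)
    protein_effects: dict = field(default_factory=dict)  # protein -> planted log2 shift
    outlier_rows: list = field(default_factory=list)  # integer row labels of plate table
    plate_fc: dict = field(default_factory=dict)  # model -> planted top-dose FC at 72 h
    tr_trajectories: dict = field(default_factory=dict)  # pathway -> log2 TR per time
    arm_ratios: dict = field(default_factory=dict)  # arm -> planted dead:viable ratio

    def to_dict(self) -> dict:
        return {
            "responder_models": list(self.responder_models),
            "differential_proteins": list(self.differential_proteins),
            "blank_proteins": list(self.blank_proteins),
            "protein_effects": dict(self.protein_effects),
            "outlier_rows": [int(i) for i in self.outlier_rows],
            "plate_fc": dict(self.plate_fc),
            "tr_trajectories": {k: list(v) for k, v in self.tr_trajectories.items()},
            "arm_ratios": dict(self.arm_ratios),
        }


def _technical_mean_noise(
    rng: np.random.Generator, sd: float, n_rep: int, shape: tuple
) -> np.ndarray:
    """Mean of ``n_rep`` technical-replicate log2 noise draws."""
    if sd == 0:
        return np.zeros(shape)
    draws = rng.normal(0.0, sd, size=(n_rep, *shape))
    return draws.mean(axis=0)


def simulate_rppa(cfg: SimConfig) -> tuple[NFIMatrix, SimTruth]:
    """Simulate a raw linear NFI matrix with planted responder effects.

    Linear NFI values are log-normal around a per-protein baseline; proteins
    in pathways with a planted ``effect_log2`` are shifted by that amount in
    responder models.  A ``blank_fraction`` of proteins is forced to near
    blank level (<= 0.02 NFI) to exercise the downstream quality filter.
    """
    rng = cfg.rng("rppa")
    pathways = cfg.pathway_assignment()
    proteins = cfg.protein_ids
    models = cfg.model_ids
    is_resp = np.array([m in cfg.responder_models for m in models], dtype=float)

    baseline = rng.normal(0.0, cfg.baseline_sd_log2, size=cfg.n_proteins)
    effects = pathways.map(lambda p: cfg.effect_log2.get(p, 0.0)).to_numpy(dtype=float)
    noise = _technical_mean_noise(
        rng, cfg.noise_sd_log2, cfg.n_technical_replicates,
        (cfg.n_proteins, cfg.n_models),
    )
    log2_vals = baseline[:, None] + np.outer(effects, is_resp) + noise
    linear = np.power(2.0, log2_vals)

    n_blank = int(round(cfg.blank_fraction * cfg.n_proteins))
    blank_idx = rng.choice(cfg.n_proteins, size=n_blank, replace=False) if n_blank else []
    blank_proteins = [proteins[i] for i in sorted(blank_idx)]
    for i in blank_idx:
        linear[i, :] = rng.uniform(0.004, 0.016, size=cfg.n_models)

    values = pd.DataFrame(linear, index=proteins, columns=models)
    matrix = NFIMatrix(values, pathways, RAW_LINEAR)
    diff = [
        p for p in proteins
        if cfg.effect_log2.get(pathways[p], 0.0) != 0.0 and p not in blank_proteins
    ]
    truth = SimTruth(
        responder_models=cfg.responder_models,
        differential_proteins=diff,
        blank_proteins=blank_proteins,
        protein_effects={p: cfg.effect_log2.get(pathways[p], 0.0) for p in proteins},
    )
    return matrix, truth


def _planted_fc(cfg: SimConfig, model: str) -> float:
    if cfg.plate_effect_fc is not None:
        return float(cfg.plate_effect_fc.get(model, 1.0))
    return 2.0 if model in cfg.responder_models else 1.0


def simulate_plate(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a long-format cytotoxicity plate table with DMSO vehicles.

    Cell death is read out as RFU.  The planted treatment effect for a model
    ramps multiplicatively with dose rank and time rank so that the highest
    dose at the last time point carries the model's full planted fold change
    over vehicle.  Outliers are injected per record with probability
    ``outlier_rate`` by multiplying the RFU by ``outlier_magnitude``; their
    row labels are recorded in the truth.
    """
    rng = cfg.rng("plate")
    rows: list = []
    n_doses, n_times = len(cfg.plate_doses), len(cfg.plate_times)
    for model in cfg.model_ids:
        fc = _planted_fc(cfg, model)
        for ti, time_h in enumerate(cfg.plate_times):
            for rep in range(1, cfg.n_replicates + 1):
                rfu = cfg.plate_base_rfu * 2.0 ** rng.normal(0, cfg.plate_noise_sd_log2)
                rows.append((model, "DMSO", 0.0, time_h, rep, rfu, True))
            for drug in cfg.drugs:
                for di, dose in enumerate(cfg.plate_doses):
                    mult = 1.0 + (fc - 1.0) * ((di + 1) / n_doses) * ((ti + 1) / n_times)
                    for rep in range(1, cfg.n_replicates + 1):
                        rfu = (
                            cfg.plate_base_rfu
                            * mult
                            * 2.0 ** rng.normal(0, cfg.plate_noise_sd_log2)
                        )
                        rows.append((model, drug, dose, time_h, rep, rfu, False))
    table = pd.DataFrame(
        rows,
        columns=["model", "drug", "dose_uM", "time_h", "replicate", "rfu", "is_vehicle"],
    )
    outlier_rows: list = []
    if cfg.outlier_rate > 0:
        hits = rng.random(len(table)) < cfg.outlier_rate
        outlier_rows = list(np.flatnonzero(hits))
        table.loc[hits, "rfu"] *= cfg.outlier_magnitude
    truth = SimTruth(
        responder_models=cfg.responder_models,
        outlier_rows=outlier_rows,
        plate_fc={m: _planted_fc(cfg, m) for m in cfg.model_ids},
    )
    return table, truth


def simulate_tr_pair(cfg: SimConfig) -> tuple[NFIMatrix, NFIMatrix, SimTruth]:
    """Simulate a treated/vehicle NFI pair over the treatment time course.

    Both matrices share per-protein baselines; the treated matrix adds the
    planted per-pathway log2 trajectory at each of the configured treatment
    times (columns).  Column labels are the times in hours.
    """
    rng = cfg.rng("tr")
    pathways = cfg.pathway_assignment()
    n_t = len(cfg.tr_times)
    baseline = rng.normal(0.0, cfg.baseline_sd_log2, size=cfg.n_proteins)
    traj = np.zeros((cfg.n_proteins, n_t))
    for i, p in enumerate(cfg.protein_ids):
        planted = cfg.tr_trajectories.get(pathways[p])
        if planted is not None:
            traj[i, :] = np.asarray(planted, dtype=float)
    noise_v = _technical_mean_noise(
        rng, cfg.tr_noise_sd_log2, cfg.n_technical_replicates, (cfg.n_proteins, n_t)
    )
    noise_t = _technical_mean_noise(
        rng, cfg.tr_noise_sd_log2, cfg.n_technical_replicates, (cfg.n_proteins, n_t)
    )
    cols = [float(t) for t in cfg.tr_times]
    vehicle = pd.DataFrame(
        np.power(2.0, baseline[:, None] + noise_v), index=cfg.protein_ids, columns=cols
    )
    treated = pd.DataFrame(
        np.power(2.0, baseline[:, None] + traj + noise_t),
        index=cfg.protein_ids,
        columns=cols,
    )
    truth = SimTruth(
        responder_models=cfg.responder_models,
        tr_trajectories={pw: tuple(v) for pw, v in cfg.tr_trajectories.items()},
    )
    return (
        NFIMatrix(treated, pathways, RAW_LINEAR),
        NFIMatrix(vehicle, pathways, RAW_LINEAR),
        truth,
    )


def simulate_killing(cfg: SimConfig) -> tuple[list[KillingRecord], SimTruth]:
    """Simulate per-imaged-PDM mask fluorescence sums for each treatment arm.

    Each arm contributes ``n_wells x n_pdm_per_well`` imaged PDM (9 by
    default).  Mask sums are drawn so that the expected dead:viable ratio
    ``(total dead - dead TIL) / viable PDM`` equals the planted per-arm
    value; per-record ratios get additive Gaussian noise truncated at zero.
    """
    rng = cfg.rng("killing")
    records: list[KillingRecord] = []
    for arm, planted in cfg.killing_arms.items():
        for well in range(1, cfg.n_wells + 1):
            for pdm in range(1, cfg.n_pdm_per_well + 1):
                viable = 1e6 * 2.0 ** rng.normal(0, 0.3)
                dead_til = (
                    0.0
                    if arm == "PDM"
                    else 2e5 * 2.0 ** rng.normal(0, 0.3)
                )
                ratio = planted
                if cfg.killing_noise_sd > 0:
                    ratio = max(planted + rng.normal(0, cfg.killing_noise_sd), 0.0)
                records.append(
                    KillingRecord(
                        arm=arm,
                        well=f"{arm}-w{well}",
                        pdm_id=f"{arm}-w{well}-pdm{pdm}",
                        fi_total_dead=dead_til + ratio * viable,
                        fi_dead_til=dead_til,
                        fi_viable_pdm=viable,
                    )
                )
    truth = SimTruth(
        responder_models=cfg.responder_models,
        arm_ratios=dict(cfg.killing_arms),
    )
    return records, truth
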