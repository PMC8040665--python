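"""Synthetic multicohort immune datasets with planted ground truth.

Emulates the structure of a three-cohort chronic-inflammation study:

* an **aging** cohort (60 older cases age 61-90, 29 young controls 22-33),
* an **HIV** cohort (24 infected, 45 uninfected controls),
* an **HCV** cohort (14 infected, 11 uninfected controls), with the
  infected individuals additionally profiled longitudinally before, during
  and after a 12-week direct-acting-antiviral regimen.

The measurement panel mirrors a mass-cytometry phospho-signaling study:
12 signaling parameters x 7 PBMC lineages (84 baseline-signaling node
features), per-stimulus response features, serum analytes and cell-subset
frequencies — 357 features in the default panel.

Measurements are generated from a linear factor model

    y = sum_d beta_d * x_d  +  lambda * f_block  +  sqrt(1 - lambda^2) * eps

where ``x_d`` are (standardized) driver covariates carrying planted effect
sizes in within-cohort SD units, ``f_block`` is a latent factor shared by a
feature's correlation community (so within-block Pearson correlation is
``lambda**2``), and ``eps`` is unit-variance Gaussian noise scaled by
``noise_sd``.  Planted effects are therefore recoverable by ordinary least
squares, and planted blocks by correlation-network community detection.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .datasets import FEATURE_COLUMNS, SUBJECT_COLUMNS, CohortDataset

__all__ = [
    "CELL_TYPES",
    "SIGNALING_PARAMS",
    "PATHWAY_OF",
    "CohortSpec",
    "CohortConfig",
    "PanelConfig",
    "EffectSpec",
    "CommunitySpec",
    "LongitudinalSpec",
    "generate_subjects",
    "generate_panel",
    "simulate_measurements",
    "simulate_longitudinal_hcv",
    "default_effects",
    "default_community_spec",
    "default_improve_features",
    "TIMEPOINT_WEEKS",
]

# ---------------------------------------------------------------------- #
# Panel vocabulary

#: The seven main PBMC lineages profiled.
CELL_TYPES = ["CD4 T", "CD8 T", "gd T", "B", "NK", "Monocytes", "DC"]

#: Signaling parameter -> pathway.  PSD = proliferation/survival/
#: differentiation, PSAV = pathogen sensing / antiviral, MAPK and STAT as
#: usually understood.
PATHWAY_OF = {
    "pCREB": "PSD",
    "pAkt": "PSD",
    "pS6": "PSD",
    "IkBa": "PSAV",
    "pIRF7": "PSAV",
    "pERK1/2": "MAPK",
    "pMAPKAPK2": "MAPK",
    "pp38": "MAPK",
    "pSTAT1": "STAT",
    "pSTAT3": "STAT",
    "pSTAT4": "STAT",
    "pSTAT5": "STAT",
}

SIGNALING_PARAMS = list(PATHWAY_OF)

STIMULI = ["IFNa", "IFNg", "IL2", "IL6", "IL7", "IL10", "IL21", "BCR"]

TIMEPOINTS = ["pre", "wk1", "wk2", "wk4", "wk8", "wk12", "post"]

#: Weeks since treatment start; "post" is the median ~9.5-month follow-up.
TIMEPOINT_WEEKS = {
    "pre": 0.0,
    "wk1": 1.0,
    "wk2": 2.0,
    "wk4": 4.0,
    "wk8": 8.0,
    "wk12": 12.0,
    "post": 53.0,
}

#: 62 circulating analytes (50-plex plus 12 extra systemic proteins).
SERUM_ANALYTES = [
    "IL-12p40", "IL-12p70", "IL-18", "IL-1b", "IL-1RA", "IL-2", "IL-4",
    "IL-5", "IL-6", "IL-7", "IL-8", "IL-10", "IL-13", "IL-15", "IL-17",
    "IL-21", "IL-22", "IL-23", "TNFa", "TNFb", "IFN-a", "IFN-g", "GM-CSF",
    "G-CSF", "M-CSF", "EGF", "FGF-2", "HGF", "NGF", "PDGF-BB", "SCF",
    "TGF-a", "TGF-b", "VEGF", "VEGFD", "Leptin", "Resistin", "PAI-1",
    "ICAM-1", "VCAM-1", "IP-10", "MIG", "MCP-1", "MCP-3", "MIP-1a",
    "MIP-1b", "RANTES", "Eotaxin", "GRO-a", "TRAIL", "sCD40L", "FasL",
    "sIL-2Ra", "sIL-6R", "sTNFR1", "sTNFR2", "CRP", "SAA", "Fibrinogen",
    "Adiponectin", "MPO", "Amyloid-P",
]

#: 43 cell-subset frequency features.
FREQUENCY_FEATURES = (
    [f"{c} frequency" for c in CELL_TYPES]
    + [
        "CD4 T memory", "CD4 T naive", "CD8 T memory", "CD8 T naive",
        "CD4 T CD28+", "CD8 T CD28+", "CD4 T Tcm", "CD4 T Tem",
        "CD4 T Temra", "CD8 T Tcm", "CD8 T Tem", "CD8 T Temra",
        "Treg", "Tfh", "CD4 T CD27+", "CD8 T CD27+", "CD4 T CD45RA+",
        "CD8 T CD45RA+", "B naive", "B memory", "B IgD+", "Plasmablast",
        "NK CD56bright", "NK CD56dim", "NK CD16+", "Monocytes classical",
        "Monocytes intermediate", "Monocytes nonclassical", "mDC", "pDC",
        "gd T Vd1", "gd T Vd2", "NKT", "MAIT", "Basophil", "ILC",
    ]
)


def _cell_of_frequency(name: str) -> str:
    """Best-effort lineage for a frequency feature (for metadata only)."""
    for c in sorted(CELL_TYPES, key=len, reverse=True):
        if name.startswith(c):
            return c
    return "none"


# ---------------------------------------------------------------------- #
# Configuration types


@dataclasses.dataclass
class CohortSpec:
    """Sizes and age ranges for one cohort's case and control groups."""

    n_cases: int
    n_controls: int
    case_age_range: tuple[int, int]
    control_age_range: tuple[int, int]

    def validate(self, name: str) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError(f"{name}: negative group size")
        for lo, hi in (self.case_age_range, self.control_age_range):
            if lo > hi:
                raise ValueError(f"{name}: inverted age range ({lo}, {hi})")


@dataclasses.dataclass
class CohortConfig:
    """Three-cohort design; defaults follow the study sizes."""

    aging: CohortSpec = dataclasses.field(
        default_factory=lambda: CohortSpec(60, 29, (61, 90), (22, 33))
    )
    hiv: CohortSpec = dataclasses.field(
        default_factory=lambda: CohortSpec(24, 45, (26, 78), (25, 78))
    )
    hcv: CohortSpec = dataclasses.field(
        default_factory=lambda: CohortSpec(14, 11, (29, 71), (18, 74))
    )
    female_fraction: float = 0.5
    cmv_prevalence: float = 0.5

    def items(self) -> list[tuple[str, CohortSpec]]:
        return [("aging", self.aging), ("hiv", self.hiv), ("hcv", self.hcv)]


@dataclasses.dataclass
class PanelConfig:
    """Feature panel layout.

    The signaling block enumerates the full ``cell_types x signaling_params``
    grid once for baseline state and once per response stimulus.
    """

    cell_types: Sequence[str] = tuple(CELL_TYPES)
    signaling_params: Sequence[str] = tuple(SIGNALING_PARAMS)
    response_stimuli: Sequence[str] = ("IFNa", "IFNg")
    serum_analytes: Sequence[str] = tuple(SERUM_ANALYTES)
    frequency_features: Sequence[str] = tuple(FREQUENCY_FEATURES)

    def validate(self) -> None:
        unknown = set(self.signaling_params) - set(PATHWAY_OF)
        if unknown:
            raise ValueError(f"unknown signaling parameters: {sorted(unknown)}")
        unknown_stim = set(self.response_stimuli) - set(STIMULI)
        if unknown_stim:
            raise ValueError(f"unknown stimuli: {sorted(unknown_stim)}")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """A planted linear driver effect, in within-cohort SD units."""

    feature_id: str
    driver: str  # age | hiv | hcv
    beta: float

    def __post_init__(self):
        if self.driver not in ("age", "hiv", "hcv"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclasses.dataclass
class CommunitySpec:
    """Latent-block assignment for correlation-community structure.

    ``blocks`` maps feature_id -> block label; ``loading`` maps feature_id
    -> lambda in [0, 1].  Within-block Pearson correlation is lambda**2.
    """

    blocks: Mapping[str, str]
    loading: Mapping[str, float]

    def __post_init__(self):
        bad = {f: l for f, l in self.loading.items() if not (0.0 <= l <= 1.0)}
        if bad:
            raise ValueError(f"loadings outside [0, 1]: {bad}")


@dataclasses.dataclass
class LongitudinalSpec:
    """Treatment-course trajectory parameters for the HCV cohort."""

    vl0: float = 1e6  # pretreatment viral load, copies/mL
    decay_rate: float = 2.0  # per-week exponential clearance
    detection_limit: float = 15.0
    pulse_cell_types: Sequence[str] = ("DC",)
    pulse_amplitude: float = 1.0  # SD units, added at wk2 only
    improve_features: Sequence[str] = ()
    improve_delta: float = 1.5  # SD units, added at post
    subject_effect: float = 0.5  # variance share of the subject intercept

    def __post_init__(self):
        if self.vl0 <= 0:
            raise ValueError("vl0 must be positive")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")


# ---------------------------------------------------------------------- #
# Generators


def generate_subjects(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw the subject table for the three cohorts.

    Ages are uniform integers within each group's range; sex and CMV
    serostatus are Bernoulli at the configured prevalences.  Deterministic
    per seed.
    """
    config = config or CohortConfig()
    rows = []
    for cohort, spec in config.items():
        spec.validate(cohort)
        rng = derive_rng(seed, "subjects", cohort)
        for group, n, (lo, hi) in (
            ("case", spec.n_cases, spec.case_age_range),
            ("control", spec.n_controls, spec.control_age_range),
        ):
            ages = rng.integers(lo, hi + 1, size=n)
            sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
            cmv = (rng.random(n) < config.cmv_prevalence).astype(int)
            for i in range(n):
                sid = f"{cohort}_{group[:4]}_{i:03d}"
                rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": sid,
                        "cohort": cohort,
                        "group": group,
                        "age": int(ages[i]),
                        "sex": sexes[i],
                        "cmv": int(cmv[i]),
                        "hiv": int(cohort == "hiv" and group == "case"),
                        "hcv": int(cohort == "hcv" and group == "case"),
                        "timepoint": "none",
                    }
                )
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def generate_panel(config: PanelConfig | None = None) -> pd.DataFrame:
    """Enumerate the feature panel as a descriptor table.

    Baseline signaling features form the exact ``len(signaling_params) x
    len(cell_types)`` grid, repeated per response stimulus for
    stim_response features.
    """
    config = config or PanelConfig()
    config.validate()
    rows = []
    for cell in config.cell_types:
        for param in config.signaling_params:
            rows.append(
                {
                    "feature_id": f"bl_{param}_{cell}",
                    "modality": "baseline_signaling",
                    "cell_type": cell,
                    "signaling_param": param,
                    "stimulus": "none",
                    "analyte": "none",
                    "pathway": PATHWAY_OF[param],
                }
            )
    for stim in config.response_stimuli:
        for cell in config.cell_types:
            for param in config.signaling_params:
                rows.append(
                    {
                        "feature_id": f"resp_{stim}_{param}_{cell}",
                        "modality": "stim_response",
                        "cell_type": cell,
                        "signaling_param": param,
                        "stimulus": stim,
                        "analyte": "none",
                        "pathway": PATHWAY_OF[param],
                    }
                )
    for analyte in config.serum_analytes:
        rows.append(
            {
                "feature_id": f"serum_{analyte}",
                "modality": "serum_protein",
                "cell_type": "none",
                "signaling_param": "none",
                "stimulus": "none",
                "analyte": analyte,
                "pathway": "none",
            }
        )
    for name in config.frequency_features:
        rows.append(
            {
                "feature_id": f"freq_{name}",
                "modality": "cell_frequency",
                "cell_type": _cell_of_frequency(name),
                "signaling_param": "none",
                "stimulus": "none",
                "analyte": "none",
                "pathway": "none",
            }
        )
    panel = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if not panel["feature_id"].is_unique:
        dupes = panel.loc[panel["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature_ids in panel: {dupes}")
    return panel


def default_community_spec(
    panel: pd.DataFrame, loading: float = 0.8
) -> CommunitySpec:
    """Four latent blocks over the baseline signaling grid, one per pathway."""
    base = panel[panel["modality"] == "baseline_signaling"]
    blocks = {r.feature_id: r.pathway for r in base.itertuples()}
    return CommunitySpec(blocks, {f: loading for f in blocks})


def default_effects(panel: pd.DataFrame) -> list[EffectSpec]:
    """A plausible planted-effect set spanning the three drivers.

    Mirrors the qualitative signatures of chronic inflammation: memory
    skewing and elevated baseline signaling with all drivers, dampened
    cytokine sensitivity (negative response betas), driver-specific serum
    elevations.  Magnitude 1 SD throughout.
    """
    ids = set(panel["feature_id"])
    effects: list[EffectSpec] = []

    def add(fid, driver, beta):
        if fid in ids:
            effects.append(EffectSpec(fid, driver, beta))

    for driver in ("age", "hiv", "hcv"):
        add("freq_CD4 T memory", driver, 1.0)
        add("freq_CD4 T naive", driver, -1.0)
        add("freq_CD8 T memory", driver, 1.0)
        add("freq_CD8 T naive", driver, -1.0)
        for cell in ("CD4 T", "CD8 T", "Monocytes"):
            add(f"bl_pSTAT1_{cell}", driver, 1.0)
            add(f"resp_IFNa_pSTAT1_{cell}", driver, -1.0)
    add("serum_IL-12p40", "age", 1.0)
    add("serum_IL-12p40", "hcv", 1.0)
    add("serum_TNFa", "age", 1.0)
    add("serum_TNFa", "hcv", 1.0)
    add("serum_IL-18", "age", 1.0)
    add("serum_IP-10", "hcv", 1.0)
    add("serum_EGF", "hcv", -1.0)
    add("freq_CD4 T frequency", "hiv", -1.0)
    add("freq_CD4 T CD28+", "hiv", -1.0)
    add("freq_CD4 T CD28+", "hcv", -1.0)
    add("freq_gd T frequency", "age", -1.0)
    add("freq_gd T frequency", "hcv", -1.0)
    return effects


def default_improve_features(panel: pd.DataFrame) -> list[str]:
    """The 13 features planted to improve after viral clearance.

    pSTAT1 response to IFN-alpha in all seven lineages, IkBa baseline in
    monocytes, IFN-gamma response in DCs, and four serum analytes.
    """
    feats = [f"resp_IFNa_pSTAT1_{c}" for c in CELL_TYPES]
    feats += ["bl_IkBa_Monocytes", "resp_IFNg_pSTAT1_DC"]
    feats += ["serum_PAI-1", "serum_EGF", "serum_IP-10", "serum_Resistin"]
    ids = set(panel["feature_id"])
    missing = [f for f in feats if f not in ids]
    if missing:
        raise ValueError(f"improve features absent from panel: {missing}")
    return feats


def _driver_design(subjects: pd.DataFrame) -> pd.DataFrame:
    """Driver covariate values used by the generator.

    Age is standardized within cohort (so planted age betas are in
    per-cohort-SD-of-age units, matching the SD scale of the response);
    HIV and HCV are 0/1 indicators.
    """
    age_z = subjects.groupby("cohort")["age"].transform(
        lambda a: (a - a.mean()) / a.std(ddof=1) if a.std(ddof=1) > 0 else 0.0
    )
    return pd.DataFrame(
        {"age": age_z.to_numpy(), "hiv": subjects["hiv"].to_numpy(),
         "hcv": subjects["hcv"].to_numpy()},
        index=subjects.index,
    )


def simulate_measurements(
    subjects: pd.DataFrame,
    panel: pd.DataFrame,
    effects: Iterable[EffectSpec] = (),
    community_spec: CommunitySpec | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    dropout: float = 0.0,
) -> CohortDataset:
    """Generate the subjects x features measurement matrix.

    See the module docstring for the generating model.  Features not named
    in ``effects`` carry beta = 0; features not in ``community_spec`` have
    loading 0 (pure noise plus driver effects).  ``dropout`` (off by
    default) marks each entry missing independently with that probability.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    effects = list(effects)
    n, m = len(subjects), len(panel)
    fid = panel["feature_id"].to_numpy()
    fpos = {f: j for j, f in enumerate(fid)}
    for e in effects:
        if e.feature_id not in fpos:
            raise ValueError(f"effect on unknown feature {e.feature_id!r}")

    rng = derive_rng(seed, "measurements")
    Y = rng.normal(0.0, 1.0, size=(n, m))

    lam = np.zeros(m)
    if community_spec is not None:
        block_labels = sorted(set(community_spec.blocks.values()))
        factors = rng.normal(0.0, 1.0, size=(n, len(block_labels)))
        bpos = {b: k for k, b in enumerate(block_labels)}
        for f, b in community_spec.blocks.items():
            if f not in fpos:
                raise ValueError(f"community spec names unknown feature {f!r}")
            j = fpos[f]
            lam[j] = community_spec.loading.get(f, 0.0)
            Y[:, j] = lam[j] * factors[:, bpos[b]] + np.sqrt(1 - lam[j] ** 2) * Y[:, j]
    Y *= noise_sd

    drivers = _driver_design(subjects)
    for e in effects:
        Y[:, fpos[e.feature_id]] += e.beta * noise_sd * drivers[e.driver].to_numpy()

    if dropout > 0:
        Y[rng.random(Y.shape) < dropout] = np.nan

    meas = pd.DataFrame(Y, columns=fid)
    return CohortDataset(meas, subjects.copy(), panel.copy())


def simulate_longitudinal_hcv(
    subjects: pd.DataFrame,
    panel: pd.DataFrame,
    spec: LongitudinalSpec | None = None,
    community_spec: CommunitySpec | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> CohortDataset:
    """Expand HCV-infected subjects over the treatment-course timepoints.

    Every infected subject is observed at all of pre, wk1, wk2, wk4, wk8,
    wk12 and post (complete panel).  Viral load decays exponentially from
    ``vl0`` and is floored at the detection limit; ``improve_features``
    shift by ``improve_delta`` at post; IFN-alpha response features of the
    pulse cell types get ``pulse_amplitude`` added at wk2 only.  A subject
    random intercept (variance share ``subject_effect``) makes the repeated
    measures properly paired.
    """
    spec = spec or LongitudinalSpec(
        improve_features=default_improve_features(panel)
    )
    if community_spec is None:
        community_spec = default_community_spec(panel)
    cases = subjects[(subjects["cohort"] == "hcv") & (subjects["group"] == "case")]
    if len(cases) == 0:
        raise ValueError("no HCV cases among subjects")
    improve = set(spec.improve_features)
    unknown = improve - set(panel["feature_id"])
    if unknown:
        raise ValueError(f"improve_features not in panel: {sorted(unknown)}")

    fid = panel["feature_id"].to_numpy()
    fpos = {f: j for j, f in enumerate(fid)}
    m = len(fid)
    pulse_mask = (
        (panel["modality"] == "stim_response")
        & (panel["stimulus"] == "IFNa")
        & panel["cell_type"].isin(list(spec.pulse_cell_types))
    )
    pulse_cols = list(np.flatnonzero(pulse_mask.to_numpy()))
    improve_cols = [fpos[f] for f in improve]

    rng = derive_rng(seed, "longitudinal")
    n_sub = len(cases)
    subj_int = rng.normal(0.0, 1.0, size=(n_sub, m))

    lam = np.zeros(m)
    bpos: dict[str, int] = {}
    if community_spec is not None:
        block_labels = sorted(set(community_spec.blocks.values()))
        bpos = {b: k for k, b in enumerate(block_labels)}
        for f, b in community_spec.blocks.items():
            if f in fpos:
                lam[fpos[f]] = community_spec.loading.get(f, 0.0)

    rows, blocks_mats, vl_rows = [], [], []
    r = float(spec.subject_effect)
    for tp in TIMEPOINTS:
        week = TIMEPOINT_WEEKS[tp]
        eps = rng.normal(0.0, 1.0, size=(n_sub, m))
        if community_spec is not None:
            factors = rng.normal(0.0, 1.0, size=(n_sub, len(bpos)))
            fac = np.zeros((n_sub, m))
            for f, b in community_spec.blocks.items():
                if f in fpos:
                    fac[:, fpos[f]] = factors[:, bpos[b]]
            eps = lam * fac + np.sqrt(1 - lam**2) * eps
        Y = np.sqrt(r) * subj_int + np.sqrt(1 - r) * eps
        Y *= noise_sd
        if tp == "wk2" and pulse_cols:
            Y[:, pulse_cols] += spec.pulse_amplitude * noise_sd
        if tp == "post" and improve_cols:
            Y[:, improve_cols] += spec.improve_delta * noise_sd
        blocks_mats.append(Y)
        vl = max(spec.vl0 * np.exp(-spec.decay_rate * week), spec.detection_limit)
        for _, s in cases.iterrows():
            sid = f"{s['subject_id']}@{tp}"
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": s["subject_id"],
                    "cohort": "hcv",
                    "group": "case",
                    "age": s["age"],
                    "sex": s["sex"],
                    "cmv": s["cmv"],
                    "hiv": 0,
                    "hcv": int(tp in ("pre", "wk1", "wk2", "wk4", "wk8", "wk12")),
                    "timepoint": tp,
                }
            )
            vl_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": s["subject_id"],
                    "timepoint": tp,
                    "week": week,
                    "viral_load": vl,
                }
            )
    meas = pd.DataFrame(np.vstack(blocks_mats), columns=fid)
    subj_table = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    vl_table = pd.DataFrame(vl_rows)
    return CohortDataset(meas, subj_table, panel.copy(), viral_load=vl_table)
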