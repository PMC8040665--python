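"""Core data container for subject-by-feature immune measurement matrices.

A :class:`CohortDataset` bundles three aligned tables:

``measurements``
    samples x features real matrix (rows indexed by ``sample_id``).
``subjects``
    one row per sample with covariates ``subject_id, cohort, group, age,
    sex, cmv, hiv, hcv, timepoint``.  For cross-sectional cohorts a sample
    is a subject (``timepoint == "none"``); for the longitudinal HCV cohort
    a sample is a (subject, timepoint) pair.
``features``
    one row per feature with descriptor columns ``feature_id, modality,
    cell_type, signaling_param, stimulus, analyte, pathway``.

Measurements are standard-score normalized *within each cohort* before any
regression, mirroring the analysis the container exists to serve.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortDataset",
    "SUBJECT_COLUMNS",
    "FEATURE_COLUMNS",
    "znormalize_within_cohort",
]

SUBJECT_COLUMNS = [
    "sample_id",
    "subject_id",
    "cohort",
    "group",
    "age",
    "sex",
    "cmv",
    "hiv",
    "hcv",
    "timepoint",
]

FEATURE_COLUMNS = [
    "feature_id",
    "modality",
    "cell_type",
    "signaling_param",
    "stimulus",
    "analyte",
    "pathway",
]

COVARIATES = ["age", "sex", "cmv", "hiv", "hcv"]


@dataclasses.dataclass
class CohortDataset:
    """Aligned measurements + subject covariates + feature metadata."""

    measurements: pd.DataFrame
    subjects: pd.DataFrame
    features: pd.DataFrame
    normalized: bool = False
    #: feature_ids excluded from downstream analysis (e.g. zero variance)
    excluded: list = dataclasses.field(default_factory=list)
    #: optional per-sample viral-load table for longitudinal cohorts
    viral_load: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        if len(self.measurements) != len(self.subjects):
            raise ValueError(
                f"measurements has {len(self.measurements)} rows but "
                f"subjects table has {len(self.subjects)}"
            )
        if self.measurements.shape[1] != len(self.features):
            raise ValueError(
                f"measurements has {self.measurements.shape[1]} columns but "
                f"features table has {len(self.features)}"
            )
        if not self.features["feature_id"].is_unique:
            dupes = self.features["feature_id"][
                self.features["feature_id"].duplicated()
            ].tolist()
            raise ValueError(f"duplicate feature_ids: {dupes}")
        self.measurements.index = pd.Index(
            self.subjects["sample_id"].to_numpy(), name="sample_id"
        )
        self.measurements.columns = pd.Index(
            self.features["feature_id"].to_numpy(), name="feature_id"
        )

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.subjects["cohort"].unique())

    def subset_features(self, feature_ids) -> "CohortDataset":
        mask = self.features["feature_id"].isin(list(feature_ids))
        return CohortDataset(
            self.measurements.loc[:, self.features.loc[mask, "feature_id"]].copy(),
            self.subjects.copy(),
            self.features.loc[mask].copy(),
            normalized=self.normalized,
            excluded=list(self.excluded),
            viral_load=self.viral_load,
        )

    def subset_samples(self, mask) -> "CohortDataset":
        mask = np.asarray(mask)
        vl = self.viral_load
        sub = self.subjects.loc[mask]
        if vl is not None:
            vl = vl[vl["sample_id"].isin(sub["sample_id"])].reset_index(drop=True)
        return CohortDataset(
            self.measurements.loc[mask].copy(),
            sub.copy(),
            self.features.copy(),
            normalized=self.normalized,
            excluded=list(self.excluded),
            viral_load=vl,
        )

    def at_timepoint(self, timepoint: str) -> "CohortDataset":
        return self.subset_samples(
            (self.subjects["timepoint"] == timepoint).to_numpy()
        )

    # ------------------------------------------------------------------ #
    # TSV round trip: subjects.tsv / features.tsv / matrix.tsv [/ viral_load.tsv]
    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "subjects": outdir / "subjects.tsv",
            "features": outdir / "features.tsv",
            "matrix": outdir / "matrix.tsv",
        }
        self.subjects.to_csv(paths["subjects"], sep="\t", index=False)
        self.features.to_csv(paths["features"], sep="\t", index=False)
        self.measurements.to_csv(paths["matrix"], sep="\t", float_format="%.10g")
        if self.viral_load is not None:
            paths["viral_load"] = outdir / "viral_load.tsv"
            self.viral_load.to_csv(paths["viral_load"], sep="\t", index=False)
        return paths

    @classmethod
    def from_tsv(cls, indir: str | Path) -> "CohortDataset":
        indir = Path(indir)
        subjects = pd.read_csv(indir / "subjects.tsv", sep="\t", dtype={"sample_id": str, "subject_id": str})
        features = pd.read_csv(indir / "features.tsv", sep="\t")
        matrix = pd.read_csv(indir / "matrix.tsv", sep="\t", index_col=0)
        matrix.index = matrix.index.astype(str)
        vl_path = indir / "viral_load.tsv"
        viral_load = (
            pd.read_csv(vl_path, sep="\t", dtype={"sample_id": str, "subject_id": str}) if vl_path.exists() else None
        )
        # align matrix rows to subjects order
        matrix = matrix.loc[subjects["sample_id"].astype(str)]
        return cls(matrix, subjects, features, viral_load=viral_load)


def znormalize_within_cohort(
    dataset: CohortDataset, tol: float = 1e-12
) -> CohortDataset:
    """Standard-score normalize each feature within each cohort.

    Per cohort and feature the sample mean is subtracted and the sample
    standard deviation (ddof=1) divided out.  Features with zero variance
    within any cohort are flagged in ``excluded`` (their values are left
    untouched there) rather than propagating NaN.  Idempotent: applying it
    to already-normalized data returns values unchanged.
    """
    meas = dataset.measurements.copy().astype(float)
    excluded: set[str] = set(dataset.excluded)
    for cohort, idx in dataset.subjects.groupby("cohort").groups.items():
        block = meas.iloc[np.asarray(idx)]
        if len(block) < 2:
            raise ValueError(f"cohort {cohort!r} has < 2 samples")
        mu = block.mean(axis=0, skipna=True)
        sd = block.std(axis=0, ddof=1, skipna=True)
        flat = sd <= tol
        excluded.update(dataset.features.loc[flat.to_numpy(), "feature_id"])
        sd = sd.where(~flat, 1.0)
        meas.iloc[np.asarray(idx)] = (block - mu) / sd
        # leave flagged features' raw values in place within this cohort
        if flat.any():
            meas.iloc[np.asarray(idx), np.flatnonzero(flat.to_numpy())] = block.loc[
                :, flat[flat].index
            ].to_numpy()
    return CohortDataset(
        meas,
        dataset.subjects.copy(),
        dataset.features.copy(),
        normalized=True,
        excluded=sorted(excluded),
        viral_load=dataset.viral_load,
    )
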