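"""Functional-domain binning of immune features and cross-driver overlap.

Significant features are mapped to named functional domains by
deterministic rules ("T cell memory skewing", "Baseline signaling in X",
"Sensitivity to C in X", "Systemic A", "<subset> frequency"), and the
per-driver significant domain sets are intersected into the seven-region
partition of a three-set Venn diagram.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import pandas as pd

__all__ = [
    "assign_domain",
    "assign_domains",
    "domain_overlap",
    "OverlapPartition",
    "shared_effect_table",
]

CELL_DISPLAY = {
    "CD4 T": "CD4+ T cells",
    "CD8 T": "CD8+ T cells",
    "gd T": "γδ T cells",
    "B": "B cells",
    "NK": "NK cells",
    "Monocytes": "monocytes",
    "DC": "DCs",
}

STIM_DISPLAY = {
    "IFNa": "IFN-α",
    "IFNg": "IFN-γ",
    "IL2": "IL-2",
    "IL6": "IL-6",
    "IL7": "IL-7",
    "IL10": "IL-10",
    "IL21": "IL-21",
    "BCR": "BCR cross-linking",
}


def _frequency_domain(descriptor) -> str:
    name = descriptor["feature_id"]
    name = name[5:] if name.startswith("freq_") else name
    low = name.lower()
    t_cell = any(t in name for t in ("CD4 T", "CD8 T", "T ")) or name.endswith(" T")
    if t_cell and any(
        k in low for k in ("memory", "naive", "tcm", "tem", "temra", "cd45ra")
    ):
        return "T cell memory skewing"
    if "cd28" in low:
        return "CD28+ T cell frequency"
    if name.endswith(" frequency"):
        cell = name[: -len(" frequency")]
        return f"{CELL_DISPLAY.get(cell, cell)} frequency"
    return f"{name} frequency"


def assign_domain(descriptor) -> str:
    """Functional domain for one feature descriptor (row or mapping).

    Total and deterministic: every valid descriptor maps to exactly one
    domain, as a pure function of its metadata fields.
    """
    modality = descriptor["modality"]
    cell = descriptor.get("cell_type", "none")
    if modality == "baseline_signaling":
        if cell in (None, "none"):
            raise ValueError("baseline_signaling feature without cell type")
        return f"Baseline signaling in {CELL_DISPLAY.get(cell, cell)}"
    if modality == "stim_response":
        stim = descriptor.get("stimulus", "none")
        if stim in (None, "none") or cell in (None, "none"):
            raise ValueError("stim_response feature needs stimulus and cell type")
        return (
            f"Sensitivity to {STIM_DISPLAY.get(stim, stim)} in "
            f"{CELL_DISPLAY.get(cell, cell)}"
        )
    if modality == "serum_protein":
        analyte = descriptor.get("analyte", "none")
        if analyte in (None, "none"):
            raise ValueError("serum_protein feature without analyte")
        return f"Systemic {analyte}"
    if modality == "cell_frequency":
        return _frequency_domain(descriptor)
    raise ValueError(f"unknown modality {modality!r}")


def assign_domains(features: pd.DataFrame) -> pd.DataFrame:
    """feature_id -> domain table for a whole panel."""
    recs = [
        {"feature_id": row["feature_id"], "domain": assign_domain(row)}
        for _, row in features.iterrows()
    ]
    return pd.DataFrame(recs)


@dataclasses.dataclass
class OverlapPartition:
    """Disjoint 7-region partition of three significant-domain sets."""

    regions: dict  # region name -> frozenset of domains
    set_names: tuple

    @property
    def counts(self) -> dict:
        return {r: len(s) for r, s in self.regions.items()}

    @property
    def total_unique(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r,
                    "count": len(s),
                    "members": ";".join(sorted(s)),
                }
                for r, s in self.regions.items()
            ]
        )


def domain_overlap(sig_domains: dict) -> OverlapPartition:
    """Partition three named domain sets into the 7 exclusive Venn regions.

    Commutative in input order; empty sets are allowed.
    """
    if len(sig_domains) != 3:
        raise ValueError("exactly three named sets required")
    names = tuple(sig_domains)
    sets = {k: set(v) for k, v in sig_domains.items()}
    regions: dict[str, frozenset] = {}
    universe = set().union(*sets.values())
    for a in names:
        others = [sets[b] for b in names if b != a]
        regions[f"{a}_only"] = frozenset(sets[a] - others[0] - others[1])
    for a, b in combinations(names, 2):
        third = next(c for c in names if c not in (a, b))
        regions[f"{a}_{b}"] = frozenset(sets[a] & sets[b] - sets[third])
    regions["all_three"] = frozenset(set.intersection(*sets.values()))
    assert sum(len(s) for s in regions.values()) == len(universe)
    return OverlapPartition(regions, names)


#: driver covariate -> cohort in which its effect is estimated
DRIVER_COHORT = {"age": "aging", "hiv": "hiv", "hcv": "hcv"}


def shared_effect_table(
    results_frame: pd.DataFrame,
    domain_map: pd.DataFrame,
    shared_domains,
) -> pd.DataFrame:
    """Signed effect sizes of significant features in shared domains.

    One row per (feature, driver) with the regression coefficient; negative
    values indicate a dampening effect of the driver.
    """
    dom = dict(zip(domain_map["feature_id"], domain_map["domain"]))
    shared = set(shared_domains)
    unknown = shared - set(dom.values())
    if unknown:
        raise ValueError(f"unknown domain names: {sorted(unknown)}")
    rows = []
    for driver, cohort in DRIVER_COHORT.items():
        sel = results_frame[
            (results_frame["cohort"] == cohort)
            & (results_frame["covariate"] == driver)
            & results_frame["significant"]
        ]
        for _, r in sel.iterrows():
            d = dom.get(r["feature_id"])
            if d in shared:
                rows.append(
                    {
                        "domain": d,
                        "feature_id": r["feature_id"],
                        "driver": driver,
                        "beta": r["beta"],
                    }
                )
    return pd.DataFrame(rows, columns=["domain", "feature_id", "driver", "beta"])
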