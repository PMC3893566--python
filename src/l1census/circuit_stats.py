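"""Circuit-level statistics: connection probabilities, morpho-electrical
cross-tabulations, putative-contact (apposition) detection, and reversal
potentials from solution recipes.

Connection probabilities come with Clopper-Pearson binomial confidence
intervals.  Directed (chemical synapse) probabilities count each ordered
direction of a probed pair as one test; undirected (gap junction)
probabilities count each pair once.  Appositions are presynaptic axon
points lying within a lateral distance threshold of postsynaptic soma or
dendrite points in the same focal plane (|dz| tolerance), deduplicated
within a merge radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import binomtest

from .morphology import AXON, DENDRITE, SOMA, Morphology

__all__ = [
    "ProbeRecord",
    "SolutionSpec",
    "connection_probability",
    "crosstab_me_types",
    "detect_appositions",
    "nernst",
    "build_report",
    "ACSF_RECIPE",
    "INTRACELLULAR_RECIPE",
]

R_GAS = 8.314462618       # J / (mol K)
FARADAY = 96485.33212     # C / mol


@dataclass
class ProbeRecord:
    """One probed (ordered or unordered) cell pair."""

    pair_id: int
    tested: bool = True
    connected: bool = False

    def __post_init__(self) -> None:
        if self.connected and not self.tested:
            raise ValueError("a connection implies the pair was tested")


@dataclass
class SolutionSpec:
    """Ionic composition (mM) of a recording solution."""

    concentrations: dict    # ion -> mM
    temperature_c: float = 34.0

    def __post_init__(self) -> None:
        for ion, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"non-positive concentration for {ion}")


#: Extracellular bath: 125 NaCl, 25 NaHCO3, 2.5 KCl, 1.25 NaH2PO4,
#: 2 CaCl2, 1 MgCl2 (total Cl- counts 2 per divalent chloride salt).
ACSF_RECIPE = {
    "K": 2.5,
    "Cl": 125.0 + 2.5 + 2 * 2.0 + 2 * 1.0,   # 133.5 mM
    "Na": 125.0 + 25.0 + 1.25,
}

#: Intracellular pipette solution: 110 K-gluconate + 10 KCl -> 120 mM K+,
#: 10 mM Cl-.
INTRACELLULAR_RECIPE = {
    "K": 110.0 + 10.0,
    "Cl": 10.0,
    "Na": 0.0,
}


def connection_probability(records, mode: str = "directed") -> dict:
    """Empirical connection probability with a 95% binomial CI.

    ``records`` is an iterable of :class:`ProbeRecord` (or any objects with
    ``tested``/``connected``) or a pair-population DataFrame from the
    generator.  In directed mode a DataFrame contributes two ordered tests
    per pair (``syn_12``, ``syn_21``); in undirected mode one test per pair
    (``gj``).
    """
    if isinstance(records, pd.DataFrame):
        if mode == "directed":
            n_tested = 2 * len(records)
            n_connected = int(records["syn_12"].sum() + records["syn_21"].sum())
        elif mode == "undirected":
            n_tested = len(records)
            n_connected = int(records["gj"].sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    else:
        records = list(records)
        tested = [r for r in records if r.tested]
        n_tested = len(tested)
        n_connected = sum(1 for r in tested if r.connected)
    if n_tested == 0:
        raise ValueError("no tested records")
    p = n_connected / n_tested
    ci = binomtest(n_connected, n_tested).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return {
        "p": p,
        "percent": 100.0 * p,
        "n_connected": n_connected,
        "n_tested": n_tested,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }


def crosstab_me_types(etypes, mtypes) -> dict:
    """Cross-tabulate e-type and m-type labels over shared cell ids.

    ``etypes``/``mtypes`` map cell id -> label (dict or Series).  Returns
    the contingency table, marginal fractions and the most frequent
    morpho-electrical combination.
    """
    e = pd.Series(etypes)
    m = pd.Series(mtypes)
    shared = e.index.intersection(m.index)
    if len(shared) == 0:
        raise ValueError("no shared cell ids between the classifications")
    e, m = e[shared], m[shared]
    table = pd.crosstab(m, e)
    table.index.name = "mtype"
    table.columns.name = "etype"
    n = len(shared)
    flat = table.stack()
    top = flat.idxmax()
    return {
        "table": table,
        "n_cells": n,
        "etype_fractions": (e.value_counts() / n).to_dict(),
        "mtype_fractions": (m.value_counts() / n).to_dict(),
        "top_combination": {
            "mtype": top[0], "etype": top[1],
            "count": int(flat.max()), "fraction": float(flat.max() / n),
        },
    }


def detect_appositions(
    pre_morph: Morphology,
    post_morph: Morphology,
    distance_threshold: float = 3.0,
    z_tolerance: float = 1.0,
    merge_radius: float = 2.0,
) -> dict:
    """Putative synaptic contacts between a presynaptic axon and a
    postsynaptic soma/dendrite.

    A candidate contact is an axon point of the presynaptic cell within
    ``distance_threshold`` um (lateral, x-y) of a soma or dendrite point of
    the postsynaptic cell with |dz| <= ``z_tolerance`` (same focal plane).
    Candidates are deduplicated by greedy merging within ``merge_radius``.
    Returns the contact list with target compartments and the somatic /
    dendritic fractions.  Disjoint arbors yield an empty map.
    """
    pre_pts = pre_morph.xyz[pre_morph.structure == AXON]
    post_mask = (post_morph.structure == SOMA) | (post_morph.structure == DENDRITE)
    post_pts = post_morph.xyz[post_mask]
    post_struct = post_morph.structure[post_mask]
    if len(pre_pts) == 0 or len(post_pts) == 0:
        return {"contacts": [], "n_contacts": 0,
                "somatic_fraction": np.nan, "dendritic_fraction": np.nan}

    tree = cKDTree(post_pts[:, :2])
    pairs = tree.query_ball_point(pre_pts[:, :2], r=distance_threshold)
    candidates = []
    for i, hits in enumerate(pairs):
        for j in hits:
            if abs(pre_pts[i, 2] - post_pts[j, 2]) <= z_tolerance:
                midpoint = (pre_pts[i] + post_pts[j]) / 2.0
                lateral = float(np.linalg.norm(pre_pts[i, :2] - post_pts[j, :2]))
                candidates.append((lateral, midpoint, int(post_struct[j])))
    candidates.sort(key=lambda c: c[0])  # closest appositions take precedence
    contacts = []
    for lateral, midpoint, struct in candidates:
        if any(np.linalg.norm(midpoint - c["position"]) < merge_radius
               for c in contacts):
            continue
        contacts.append({
            "position": midpoint,
            "target_compartment": "soma" if struct == SOMA else "dendrite",
            "lateral_distance": lateral,
        })
    n = len(contacts)
    n_soma = sum(1 for c in contacts if c["target_compartment"] == "soma")
    return {
        "contacts": contacts,
        "n_contacts": n,
        "somatic_fraction": n_soma / n if n else np.nan,
        "dendritic_fraction": (n - n_soma) / n if n else np.nan,
    }


def nernst(ion_valence: int, c_in: float, c_out: float,
           temperature_c: float = 34.0) -> float:
    """Nernst reversal potential in mV: E = (RT / zF) ln(c_out / c_in)."""
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    if ion_valence == 0:
        raise ValueError("ion valence must be nonzero")
    t_kelvin = temperature_c + 273.15
    return float(
        R_GAS * t_kelvin / (ion_valence * FARADAY) * np.log(c_out / c_in) * 1e3
    )


def build_report(stages: dict, seeds: dict | None = None,
                 config: dict | None = None) -> str:
    """Stable-key-order JSON summary of the pipeline stage outputs.

    ``stages`` maps stage name -> serializable summary (missing optional
    stages may be None and are marked as gaps).  A reproducibility block
    records seeds, the configuration, and library versions.
    """
    import sklearn
    import scipy
    import l1census

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, pd.DataFrame):
            return _clean(obj.to_dict())
        if isinstance(obj, pd.Series):
            return _clean(obj.to_dict())
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return obj

    body = {
        "reproducibility": {
            "seeds": _clean(seeds or {}),
            "config": _clean(config or {}),
            "versions": {
                "l1census": l1census.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "sklearn": sklearn.__version__,
                "pandas": pd.__version__,
            },
        },
        "stages": {
            name: (_clean(value) if value is not None else "not run")
            for name, value in stages.items()
        },
    }
    return json.dumps(body, indent=2, sort_keys=True)
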