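"""End-to-end conveniences tying the modules together.

These helpers run the canonical processing order — detrend, nuisance
regression, band-pass, correlation matrix — per subject, convert connectomes
to weighted graphs, and assemble the tidy metric table the association stage
consumes.  They are what the command-line interface and the test/acceptance
harnesses call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import AnalysisConfig, run_full_analysis
from .connectome import (
    FunctionalConnectome,
    StructuralConnectome,
    build_correlation_matrix,
    directed_connection_probabilities,
    symmetrize_connection_matrix,
)
from .graph import WeightedGraph, WeightPolicy, compute_metric_table
from .preprocess import bandpass, detrend_and_regress
from .simulate import SyntheticCohort

__all__ = [
    "functional_connectome_from_timeseries",
    "structural_connectome_from_counts",
    "cohort_functional_connectomes",
    "cohort_structural_connectomes",
    "cohort_metric_table",
    "cohort_association",
]

BAND_HZ = (0.01, 0.1)


def functional_connectome_from_timeseries(ts, nuis=None, band=BAND_HZ) -> FunctionalConnectome:
    """Detrend -> nuisance regression -> band-pass -> Pearson correlation matrix."""
    cleaned = detrend_and_regress(ts, nuis)
    filtered = bandpass(cleaned, *band)
    return build_correlation_matrix(filtered)


def structural_connectome_from_counts(counts) -> StructuralConnectome:
    """Streamline counts -> directed probabilities -> undirected average."""
    directed = directed_connection_probabilities(counts)
    return symmetrize_connection_matrix(directed, counts.region_labels)


def cohort_functional_connectomes(cohort: SyntheticCohort) -> dict[str, WeightedGraph]:
    out = {}
    for subject, ts, nuis in zip(cohort.subjects, cohort.timeseries, cohort.nuisance):
        fc = functional_connectome_from_timeseries(ts, nuis)
        out[subject] = WeightedGraph(fc.matrix, fc.region_labels)
    return out


def cohort_structural_connectomes(cohort: SyntheticCohort) -> dict[str, WeightedGraph]:
    out = {}
    for subject, counts in zip(cohort.subjects, cohort.streamline_counts):
        sc = structural_connectome_from_counts(counts)
        out[subject] = WeightedGraph(sc.matrix, sc.region_labels)
    return out


def cohort_metric_table(
    cohort: SyntheticCohort,
    modality: str = "functional",
    policy: WeightPolicy | None = None,
    global_only: bool = False,
) -> pd.DataFrame:
    """Tidy per-subject metric table for one modality of a synthetic cohort.

    ``global_only`` skips the nodal measures (useful when only the three
    global associations are of interest — the nodal sweep is 270 extra
    series per subject).
    """
    if modality == "functional":
        graphs = cohort_functional_connectomes(cohort)
    elif modality == "structural":
        graphs = cohort_structural_connectomes(cohort)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    scopes = ("global",) if global_only else ("global", "nodal")
    return compute_metric_table(graphs, policy, scopes=scopes)


def cohort_association(
    cohort: SyntheticCohort,
    modality: str = "functional",
    config: AnalysisConfig | None = None,
    policy: WeightPolicy | None = None,
    global_only: bool = False,
    behaviours: list[str] | None = None,
) -> pd.DataFrame:
    """Metric table + behavioural table + confounds -> association results."""
    metrics = cohort_metric_table(cohort, modality, policy, global_only=global_only)
    behaviour = cohort.behaviour if behaviours is None else cohort.behaviour[behaviours]
    return run_full_analysis(metrics, behaviour, cohort.confounds, config)
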