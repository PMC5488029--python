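"""End-to-end orchestration: traces -> scored matrix -> analysis.

``score_dataset`` implements the full scoring path — align every trace on
its internal standards, detect peaks above the fluorescence threshold,
build migration-time bins from replicate runs, merge them into one
reference bin set, score every sample, form per-individual consensus rows
and run duplicate QC. ``analyze_matrix`` takes any binary matrix (scored
here or imported) through polymorphic filtering, diversity statistics,
Bray-Curtis, NMDS and marker-vector fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import binning, diversity, qc
from .config import RunConfig
from .exceptions import EmptyAnalysisError, StandardsNotFoundError, ValidationError
from .matrix import BinaryMatrix
from .ordination import MarkerVectorFit, OrdinationResult, fit_marker_vectors, nmds
from .trace import (
    StandardPair,
    Trace,
    align_to_reference,
    default_windows,
    detect_peaks,
    locate_internal_standards,
    restrict_to_scoreable_range,
)

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    """Everything the scoring stage produces."""

    matrix: BinaryMatrix  # consensus rows, replicate rows attached
    qc_matrix: BinaryMatrix  # after error-prone marker exclusion
    bins: binning.BinSet
    qc_report: qc.QCReport
    unassigned: dict[str, list]  # sample_id -> peaks outside every bin
    flagged_samples: list[str]  # samples whose standards were not found
    groups: pd.Series  # individual_id -> group label
    stages: list[dict] = field(default_factory=list)  # machine-readable stage log


@dataclass
class AnalysisResult:
    """Everything the analysis stage produces."""

    matrix: BinaryMatrix  # polymorphic markers only
    frequencies: pd.Series
    richness: pd.Series
    shannon: dict
    phenotypes: diversity.PhenotypeTable
    distances: object  # skbio DistanceMatrix
    ordination: OrdinationResult
    vector_fits: list[MarkerVectorFit]


def _prepare_sample(
    trace: Trace, reference: StandardPair | None, cfg: RunConfig
) -> tuple[list, StandardPair]:
    """Locate standards, align, detect and range-restrict one sample's peaks."""
    lo_win, hi_win = default_windows(trace, cfg.standards.window_fraction)
    own = locate_internal_standards(
        trace, lo_win, hi_win, min_height=cfg.detection.min_height_fu
    )
    ref = reference if reference is not None else own
    aligned = align_to_reference(trace, own, ref)
    peaks = detect_peaks(
        aligned,
        min_height=cfg.detection.min_height_fu,
        min_prominence=cfg.detection.min_prominence_fu,
        min_separation=cfg.detection.min_separation_s,
    )
    peaks = restrict_to_scoreable_range(
        peaks, aligned.standards, margin=cfg.detection.min_separation_s
    )
    return peaks, ref


def score_dataset(
    traces: dict[str, Trace],
    manifest: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> ScoreResult:
    """Score a set of replicated traces into a QC-filtered binary matrix.

    ``manifest`` needs columns sample_id, individual_id, replicate_id,
    group. Samples whose internal standards cannot be located are flagged
    and excluded while the run continues; if every sample is flagged the
    dataset is unusable and a :class:`StandardsNotFoundError` is raised.

    The reference time scale is taken from the configured reference
    standard times, or from the first sample whose standards are found.
    """
    cfg = cfg or RunConfig()
    stages: list[dict] = []
    reference = None
    if cfg.standards.reference_lower_s is not None:
        reference = StandardPair(
            lower_time=cfg.standards.reference_lower_s,
            upper_time=cfg.standards.reference_upper_s,
        )

    peaks_by_sample: dict[str, list] = {}
    flagged: list[str] = []
    for row in manifest.itertuples():
        trace = traces[row.sample_id]
        try:
            peaks, reference = _prepare_sample(trace, reference, cfg)
        except StandardsNotFoundError as exc:
            logger.warning("flagging sample %s: %s", row.sample_id, exc)
            flagged.append(row.sample_id)
            continue
        peaks_by_sample[row.sample_id] = peaks
    if not peaks_by_sample:
        raise StandardsNotFoundError("no sample yielded internal standards")
    stages.append(
        {"stage": "detect", "n_samples": len(peaks_by_sample), "n_flagged": len(flagged)}
    )

    usable = manifest[~manifest["sample_id"].isin(flagged)]

    # --- bin construction from replicate runs -----------------------------
    # only individuals actually run in replicate contribute to the bins;
    # singly-run samples are scored against them afterwards
    rep_counts = usable.groupby("individual_id")["sample_id"].size()
    duplicated = usable[usable["individual_id"].map(rep_counts) >= 2]
    bin_sets = []
    if cfg.binning.granularity == "group":
        grouping = duplicated.groupby("group", sort=False)
    else:
        grouping = duplicated.groupby("individual_id", sort=False)
    for _, rows in grouping:
        replicate_lists = [peaks_by_sample[s] for s in rows["sample_id"]]
        if len(replicate_lists) < 2:
            continue
        clusters = binning.cluster_replicate_peaks(replicate_lists, gap=cfg.binning.gap_s)
        bin_sets.append(
            binning.build_bins(
                clusters,
                k_sd=cfg.binning.k_sd,
                min_half_width=cfg.binning.min_half_width_s,
                min_support=cfg.binning.min_support,
                max_half_width=cfg.binning.max_half_width_s,
            )
        )
    if not bin_sets:
        raise ValidationError("no replicated runs available to build bins from")
    bins = binning.merge_bin_sets(bin_sets)
    stages.append(
        {
            "stage": "bins",
            "n_bin_sets": len(bin_sets),
            "n_markers_built": sum(len(b) for b in bin_sets),
            "n_markers_merged": len(bins),
        }
    )

    # --- scoring ----------------------------------------------------------
    replicate_rows: dict[tuple[str, int], dict[str, int]] = {}
    unassigned: dict[str, list] = {}
    for row in usable.itertuples():
        profile, missed = binning.score_profile(peaks_by_sample[row.sample_id], bins)
        replicate_rows[(row.individual_id, int(row.replicate_id))] = profile
        if missed:
            unassigned[row.sample_id] = missed
    rep_df = pd.DataFrame.from_dict(replicate_rows, orient="index")
    rep_df.index = pd.MultiIndex.from_tuples(rep_df.index, names=["individual_id", "replicate_id"])
    rep_df = rep_df.reindex(columns=bins.labels).fillna(0)

    consensus = {
        str(ind): qc.consensus_profile(rows.droplevel(0))
        for ind, rows in rep_df.groupby(level=0, sort=False)
    }
    order = usable["individual_id"].drop_duplicates()
    data = pd.DataFrame.from_dict(consensus, orient="index").loc[order]
    matrix = BinaryMatrix(data=data, replicates=rep_df)
    stages.append(
        {
            "stage": "score",
            "n_individuals": matrix.n_individuals,
            "n_markers": matrix.n_markers,
            "n_samples_with_unassigned": len(unassigned),
        }
    )

    # --- duplicate QC -----------------------------------------------------
    qc_matrix, report = qc.run_qc(matrix, threshold=cfg.qc.mismatch_threshold)
    stages.append(
        {
            "stage": "qc",
            "n_discarded": len(report.discarded_markers),
            "error_rate_before": report.error_rate_before,
            "error_rate_after": report.error_rate_after,
        }
    )

    groups = usable.drop_duplicates("individual_id").set_index("individual_id")["group"]
    return ScoreResult(
        matrix=matrix,
        qc_matrix=qc_matrix,
        bins=bins,
        qc_report=report,
        unassigned=unassigned,
        flagged_samples=flagged,
        groups=groups,
        stages=stages,
    )


def analyze_matrix(
    matrix: BinaryMatrix,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> AnalysisResult:
    """Diversity, ordination and marker-vector analysis of a binary matrix.

    Fixed and all-absent markers are dropped first; if nothing polymorphic
    remains the analysis is refused explicitly.
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    poly = qc.drop_fixed_markers(matrix)
    if poly.n_markers == 0:
        raise EmptyAnalysisError("no polymorphic markers remain after filtering")
    k = cfg.ordination.dimensions
    if poly.n_individuals < k + 2:
        raise ValidationError(
            f"need at least {k + 2} individuals for a {k}-dimensional ordination"
        )
    freqs = diversity.marker_frequencies(poly)
    rich = diversity.richness(poly)
    shannon = diversity.shannon_summary(poly)
    phenos = diversity.phenotype_table(poly)
    dm = diversity.bray_curtis(poly)
    ordination = nmds(
        dm,
        k=k,
        n_starts=cfg.ordination.n_starts,
        max_iter=cfg.ordination.max_iter,
        tol=cfg.ordination.tol,
        seed=seed,
    )
    fits = fit_marker_vectors(
        ordination, poly, n_perm=cfg.ordination.permutations, seed=seed
    )
    return AnalysisResult(
        matrix=poly,
        frequencies=freqs,
        richness=rich,
        shannon=shannon,
        phenotypes=phenos,
        distances=dm,
        ordination=ordination,
        vector_fits=fits,
    )
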