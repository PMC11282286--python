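"""Recovery statistics for demixed videos.

Quality of a demixing run is judged against ground truth with two Pearson
correlation tables: ν (GT traces vs NMF traces) and γ (GT traces vs GT
traces). Sources are greedily assigned to components in descending order of
ν and the assigned diagonal is summarized as δ_avg ± σ_δ. Cross-talk beyond
the intrinsic GT–GT correlation is the absolute error

    AE_ij = |ν_ij − γ_ij|   (i ≠ j)

summarized as ζ_avg = mean(AE_ij) and σ_ζ = std(AE_ij) over the evaluated
subset; both should approach zero for a perfect experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import SourceSet, VideoStack
from .demix import DemixResult

__all__ = [
    "CorrelationTable",
    "DiagonalSummary",
    "CrosstalkSummary",
    "EvaluationReport",
    "pearson_table",
    "assign_and_sort",
    "diagonal_summary",
    "crosstalk_summary",
    "fingerprint_match",
    "ensemble_trace",
    "evaluate_demix",
]


@dataclass
class CorrelationTable:
    """Pearson correlations between two trace families, fraction scale."""

    values: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.row_labels:
            self.row_labels = list(range(self.values.shape[0]))
        if not self.col_labels:
            self.col_labels = list(range(self.values.shape[1]))
        if (len(self.row_labels), len(self.col_labels)) != self.values.shape:
            raise ValueError("label lengths must match the table shape")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("Pearson coefficients must lie in [-1, 1]")


@dataclass
class DiagonalSummary:
    """Assigned-diagonal statistics δ over an evaluated source subset."""

    per_source_diagonals: np.ndarray
    delta_avg: float
    sigma_delta: float
    subset: list


@dataclass
class CrosstalkSummary:
    """Off-diagonal absolute-error statistics ζ over a source subset."""

    ae_matrix: np.ndarray
    zeta_avg: float
    sigma_zeta: float
    subset: list


@dataclass
class EvaluationReport:
    gt_nmf: CorrelationTable
    gt_gt: CorrelationTable
    assignment: dict[int, int]
    sorted_sources: list[int]
    diagonal: DiagonalSummary
    crosstalk: CrosstalkSummary | None
    fingerprint_correlations: np.ndarray
    n_sources: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant trace encountered; correlation set to 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pearson_table(traces_a, traces_b, row_labels=None, col_labels=None) -> CorrelationTable:
    """Pearson correlation of every trace in A against every trace in B.

    Constant traces correlate 0 with a warning (the coefficient is undefined
    for them). All traces must share one length >= 3.
    """
    A = [np.asarray(t, dtype=float) for t in traces_a]
    B = [np.asarray(t, dtype=float) for t in traces_b]
    lengths = {t.shape[0] for t in A} | {t.shape[0] for t in B}
    if len(lengths) != 1:
        raise ValueError(f"trace length mismatch: {sorted(lengths)}")
    if lengths.pop() < 3:
        raise ValueError("traces must have length >= 3")
    values = np.array([[_pearson(a, b) for b in B] for a in A])
    return CorrelationTable(values=values, row_labels=list(row_labels or []),
                            col_labels=list(col_labels or []))


def assign_and_sort(gt_nmf: CorrelationTable) -> tuple[dict[int, int], list[int]]:
    """Greedy descending-correlation matching of GT sources to components.

    Repeatedly takes the globally largest remaining table entry and assigns
    that GT source to that component, removing both from contention; exact
    ties break toward the lowest (row, col). Returns the assignment (GT row
    -> component column) and GT rows sorted by descending assigned
    correlation. GT sources left without a component (when there are fewer
    components than sources) are unassigned, i.e. unrecovered.
    """
    table = gt_nmf.values.copy()
    n_g, n_c = table.shape
    if table.size == 0:
        raise ValueError("empty correlation table")
    assignment: dict[int, int] = {}
    masked = table.copy()
    for _ in range(min(n_g, n_c)):
        flat = np.argmax(masked)  # row-major: lowest (row, col) wins ties
        i, j = divmod(int(flat), n_c)
        if masked[i, j] == -np.inf:
            break
        assignment[i] = j
        masked[i, :] = -np.inf
        masked[:, j] = -np.inf
    order = sorted(assignment, key=lambda i: -table[i, assignment[i]])
    return assignment, order


def diagonal_summary(
    gt_nmf: CorrelationTable,
    assignment: dict[int, int],
    subset: list[int] | None = None,
    population_std: bool = True,
) -> DiagonalSummary:
    """δ statistics: assigned diagonal values over ``subset`` GT sources.

    ``subset`` defaults to all assigned sources. The standard deviation is
    the population convention (divide by n) unless ``population_std`` is
    False.
    """
    if subset is None:
        subset = sorted(assignment)
    if not subset:
        raise ValueError("empty evaluation subset")
    missing = [i for i in subset if i not in assignment]
    if missing:
        raise ValueError(f"subset sources {missing} are unassigned")
    diags = np.array([gt_nmf.values[i, assignment[i]] for i in subset])
    ddof = 0 if population_std else 1
    return DiagonalSummary(
        per_source_diagonals=diags,
        delta_avg=float(diags.mean()),
        sigma_delta=float(diags.std(ddof=ddof)) if diags.size > ddof else 0.0,
        subset=list(subset),
    )


def crosstalk_summary(
    gt_nmf: CorrelationTable,
    gt_gt: CorrelationTable,
    subset: list[int],
    population_std: bool = True,
    printed_prefactor: bool = False,
) -> CrosstalkSummary:
    """ζ statistics: off-diagonal |ν − γ| over the subset.

    Both tables must be square over the same source labels (ν reindexed so
    column j is the component assigned to source j). ζ_avg is the plain
    arithmetic mean of the off-diagonal absolute errors; the alternative
    1/(2(N_s−1))·Σ prefactor is available for comparison via
    ``printed_prefactor`` but is not the default (it does not average for
    general subset sizes).
    """
    if gt_nmf.values.shape != gt_gt.values.shape:
        raise ValueError("ν and γ tables must have the same shape")
    if gt_nmf.values.shape[0] != gt_nmf.values.shape[1]:
        raise ValueError("crosstalk needs square tables over one source set")
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("crosstalk needs at least 2 sources (no off-diagonal else)")
    nu = gt_nmf.values[np.ix_(subset, subset)]
    ga = gt_gt.values[np.ix_(subset, subset)]
    ae = np.abs(nu - ga)
    off = ~np.eye(len(subset), dtype=bool)
    vals = ae[off]
    if printed_prefactor:
        zeta = float(vals.sum() / (2.0 * (len(subset) - 1)))
    else:
        zeta = float(vals.mean())
    ddof = 0 if population_std else 1
    return CrosstalkSummary(
        ae_matrix=np.where(off, ae, 0.0),
        zeta_avg=zeta,
        sigma_zeta=float(vals.std(ddof=ddof)),
        subset=subset,
    )


def fingerprint_match(
    gt_fingerprints, nmf_components, assignment: dict[int, int]
) -> np.ndarray:
    """Spatial Pearson correlation of each assigned GT/NMF fingerprint pair.

    Images are flattened and max-normalized first (Pearson is scale
    invariant, so this only guards against degenerate all-zero images).
    """
    gt = [np.asarray(getattr(fp, "image", fp), dtype=float) for fp in gt_fingerprints]
    comp = [np.asarray(c, dtype=float) for c in nmf_components]
    out = np.full(len(gt), np.nan)
    for i, j in assignment.items():
        a, b = gt[i], comp[j]
        if a.shape != b.shape:
            raise ValueError(f"image size mismatch for pair ({i}, {j}): {a.shape} vs {b.shape}")
        am = a.max()
        bm = b.max()
        a = a / am if am > 0 else a
        b = b / bm if bm > 0 else b
        out[i] = _pearson(a.ravel(), b.ravel())
    return out


def ensemble_trace(video: VideoStack) -> np.ndarray:
    """Photometry-style ensemble trace: per-frame sum of all pixel counts."""
    return video.frames.reshape(video.n_frames, -1).sum(axis=1).astype(float)


def evaluate_demix(
    sources: SourceSet,
    result: DemixResult,
    subset_size: int | None = None,
    gt_indices: list[int] | None = None,
    population_std: bool = True,
) -> EvaluationReport:
    """Full evaluation of a demixing run against ground truth.

    ``gt_indices`` restricts the evaluation to a subset of GT sources (e.g.
    targets only); ``subset_size`` keeps the k best-assigned sources for the
    δ/ζ summaries ("first k beads" in sorted order). The ν table used for ζ
    is reindexed so that column j holds the component assigned to source j.
    """
    if gt_indices is None:
        gt_indices = list(range(sources.n_sources))
    gt_traces = [sources.traces[i] for i in gt_indices]
    nmf_traces = list(result.temporal_components)

    gt_nmf = pearson_table(gt_traces, nmf_traces, row_labels=list(gt_indices))
    gt_gt = pearson_table(gt_traces, gt_traces, row_labels=list(gt_indices),
                          col_labels=list(gt_indices))
    assignment, order = assign_and_sort(gt_nmf)

    subset = order[:subset_size] if subset_size else list(order)
    diag = diagonal_summary(gt_nmf, assignment, subset, population_std)

    crosstalk = None
    if len(subset) >= 2:
        # square ν over the subset: entry (i, j) = corr(GT_i, component assigned to GT_j)
        nu_sq = np.array(
            [[gt_nmf.values[i, assignment[j]] for j in subset] for i in subset]
        )
        ga_sq = gt_gt.values[np.ix_(subset, subset)]
        labels = [gt_indices[i] for i in subset]
        crosstalk = crosstalk_summary(
            CorrelationTable(nu_sq, labels, labels),
            CorrelationTable(ga_sq, labels, labels),
            list(range(len(subset))),
            population_std,
        )

    comp_shape = result.spatial_components.shape[1:]
    if comp_shape == sources.image_shape:
        fp_corr = fingerprint_match(
            [sources.fingerprints[gt_indices[i]] for i in range(len(gt_indices))],
            list(result.spatial_components),
            assignment,
        )
    else:  # binned analysis: component images are at a different resolution
        fp_corr = np.full(len(gt_indices), np.nan)
    return EvaluationReport(
        gt_nmf=gt_nmf,
        gt_gt=gt_gt,
        assignment=assignment,
        sorted_sources=order,
        diagonal=diag,
        crosstalk=crosstalk,
        fingerprint_correlations=fp_corr,
        n_sources=sources.n_sources,
    )
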