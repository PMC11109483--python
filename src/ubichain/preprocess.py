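"""Preprocessing chain for pulldown quantification matrices.

Fixed order: flag filtering -> dropout-sample removal -> valid-value
filtering -> log2 + median normalization -> downshifted-normal imputation.
Rerunning with the same seed reproduces the output bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import IntensityMatrix, ProteinRecord, SampleDesign


def drop_flagged(
    matrix: IntensityMatrix, records: list[ProteinRecord]
) -> tuple[IntensityMatrix, list[ProteinRecord]]:
    """Remove reverse / contaminant / site-only rows before any statistic."""
    if len(records) != matrix.n_proteins:
        raise ValueError("records do not align with matrix rows")
    keep = [r.protein_id for r in records if not r.flagged]
    n_dropped = matrix.n_proteins - len(keep)
    if not keep:
        warnings.warn("all rows flagged; returning an empty matrix")
        return matrix.subset_proteins([]), []
    if n_dropped:
        warnings.warn(f"removed {n_dropped} flagged row(s)")
    kept_records = [r for r in records if not r.flagged]
    return matrix.subset_proteins(keep), kept_records


def detect_dropout_samples(
    matrix: IntensityMatrix, design: SampleDesign, min_fraction: float = 0.5
) -> list[str]:
    """Flag samples whose detection count collapsed relative to their dataset.

    A sample is a dropout when its number of present values is below
    ``min_fraction`` times the median present-count of samples in the same
    dataset.  Raises if removing the flagged samples would leave any bait
    group with fewer than 2 samples.
    """
    counts = dict(zip(matrix.sample_ids, matrix.present_per_sample()))
    flagged: list[str] = []
    for ds in design.datasets():
        ds_samples = [s for s in design.subset(ds).sample_ids if s in counts]
        med = float(np.median([counts[s] for s in ds_samples]))
        flagged += [s for s in ds_samples if counts[s] < min_fraction * med]
    if flagged:
        remaining = design.drop_samples(flagged)
        for ds in remaining.datasets():
            for bait, n in remaining.group_sizes(ds).items():
                if n < 2:
                    raise ValueError(
                        f"dropout removal leaves group {bait!r} in dataset {ds!r} "
                        f"with {n} sample(s)"
                    )
    return flagged


def remove_samples(
    matrix: IntensityMatrix, design: SampleDesign, sample_ids: list[str]
) -> tuple[IntensityMatrix, SampleDesign]:
    keep = [s for s in matrix.sample_ids if s not in set(sample_ids)]
    return matrix.subset_samples(keep), design.drop_samples(sample_ids)


def filter_min_valid(
    matrix: IntensityMatrix, design: SampleDesign, min_valid: int = 3
) -> IntensityMatrix:
    """Keep proteins with >= min_valid present values in at least one bait group.

    The bead control counts as a group, so pure background binders survive to
    be tested (and rejected) rather than silently vanishing; bait-exclusive
    binders — the objects of interest — are retained by their own group.
    """
    present = ~matrix.missing
    keep = np.zeros(matrix.n_proteins, dtype=bool)
    for ds in design.datasets():
        for bait, n in design.subset(ds).group_sizes().items():
            samples = design.samples_for(bait, ds)
            samples = [s for s in samples if s in set(matrix.sample_ids)]
            if min_valid > len(samples):
                raise ValueError(
                    f"min_valid={min_valid} exceeds the size of group {bait!r} ({len(samples)})"
                )
            idx = matrix.sample_index(samples)
            keep |= present[:, idx].sum(axis=1) >= min_valid
    return matrix.subset_proteins([p for p, k in zip(matrix.protein_ids, keep) if k])


def log2_median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Log2-transform and shift each sample so its median matches the grand
    median of per-sample medians.  The mask is untouched; any constant anchor
    leaves downstream mean differences unchanged (shift invariance)."""
    if matrix.scale != "linear":
        raise ValueError("normalization expects a linear-scale matrix")
    logm = matrix.to_log2()
    n_present = logm.present_per_sample()
    if np.any(n_present == 0):
        empty = [s for s, n in zip(logm.sample_ids, n_present) if n == 0]
        raise ValueError(f"sample(s) with no present values (drop first): {empty}")
    medians = np.nanmedian(logm.values, axis=0)
    target = float(np.median(medians))
    values = logm.values - medians[None, :] + target
    return IntensityMatrix(
        list(logm.protein_ids), list(logm.sample_ids), values, logm.missing.copy(), "log2"
    )


def impute_downshift(
    matrix: IntensityMatrix, width: float = 0.3, shift: float = 1.8, seed=0
) -> tuple[IntensityMatrix, np.ndarray]:
    """Replace missing cells with draws from a narrowed, left-shifted Normal.

    Per sample s with present-value mean m_s and SD sd_s, each missing cell is
    drawn independently from Normal(m_s - shift*sd_s, (width*sd_s)^2) —
    modelling values lost at the detection limit.  Returns the completed
    matrix and the imputation provenance mask (True where a cell was drawn).
    Present cells are never altered.
    """
    if matrix.scale != "log2":
        raise ValueError("downshift imputation expects a log2-scale matrix")
    n_present = matrix.present_per_sample()
    if np.any(n_present < 2):
        bad = [s for s, n in zip(matrix.sample_ids, n_present) if n < 2]
        raise ValueError(f"sample(s) with < 2 present values cannot be imputed: {bad}")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    imputed = matrix.missing.copy()
    for j in range(matrix.n_samples):
        col = values[:, j]
        present = ~matrix.missing[:, j]
        m = float(np.mean(col[present]))
        sd = float(np.std(col[present], ddof=1))
        miss = matrix.missing[:, j]
        if miss.any():
            col[miss] = rng.normal(m - shift * sd, width * sd, size=int(miss.sum()))
    return (
        IntensityMatrix(
            list(matrix.protein_ids), list(matrix.sample_ids),
            values, np.zeros_like(imputed), "log2",
        ),
        imputed,
    )


@dataclass
class PreprocessReport:
    """Counts at each filtering stage, for the run log."""

    n_input: int = 0
    n_flagged: int = 0
    dropout_samples: list[str] = field(default_factory=list)
    n_after_valid_filter: int = 0


def run_preprocess(
    matrix: IntensityMatrix,
    records: list[ProteinRecord],
    design: SampleDesign,
    min_fraction: float = 0.5,
    min_valid: int = 3,
    width: float = 0.3,
    shift: float = 1.8,
    seed=0,
) -> tuple[IntensityMatrix, IntensityMatrix, np.ndarray, PreprocessReport]:
    """Full chain.  Returns (processed log2 matrix, raw filtered linear matrix,
    imputation mask, report).  The raw filtered matrix (post valid-value
    filter, pre-normalization) is what the two-pass prefilter re-processes.
    """
    report = PreprocessReport(n_input=matrix.n_proteins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, records = drop_flagged(matrix, records)
    report.n_flagged = report.n_input - matrix.n_proteins
    dropouts = detect_dropout_samples(matrix, design, min_fraction)
    if dropouts:
        matrix, design = remove_samples(matrix, design, dropouts)
    report.dropout_samples = dropouts
    raw_filtered = filter_min_valid(matrix, design, min_valid)
    report.n_after_valid_filter = raw_filtered.n_proteins
    normalized = log2_median_normalize(raw_filtered)
    processed, imputed = impute_downshift(normalized, width=width, shift=shift, seed=seed)
    return processed, raw_filtered, imputed, report
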