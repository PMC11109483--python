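"""Chain-specificity inference: prefilter, cross-bait selection, clustering,
interactome correlation, and the linkage / length / branch classification rules.

The prefilter is two-pass.  Pass 1 normalizes and imputes the full
valid-value-filtered matrix and tests every chain bait against the bead-only
control (two-sample moderated t); proteins significantly enriched on at least
one bait (adj_p < alpha, logFC > 0) are retained.  Pass 2 subsets the
*pre-normalization* matrix to the retained proteins and re-normalizes and
re-imputes it, so the working matrix is conditioned only on ubiquitin-enriched
proteins.  The two imputations use independent seed substreams.

Classification rules are pure functions of contrast tables:

- linkage: K48_Ub3 vs K63_Ub3 moderated t; significant positive -> K48
  preference, significant negative -> K63.
- length: Ub3 vs Ub2 per linkage; significant in >= 1 dataset with a
  consistent fold-change direction in every dataset (|logFC| > 0.5 for K48,
  sign consistency only for K63).
- branch: the branched trimer against both homotypic trimers (and optionally
  both dimers); both significant positive -> branch-specific, all four in
  every dataset -> strict tier; both significant negative -> homotypic
  preference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .io import IntensityMatrix, SampleDesign
from .modstats import (
    ContrastResult,
    GroupFit,
    VariancePrior,
    estimate_variance_prior,
    fit_groups,
    moderated_F,
    moderated_t,
)
from .preprocess import impute_downshift, log2_median_normalize

CALL_LEVELS = (
    "ub_enriched_only",
    "linkage_K48",
    "linkage_K63",
    "length_Ub3_K48",
    "length_Ub3_K63",
    "length_Ub2_preferring",
    "branch_specific",
    "branch_specific_strict",
    "homotypic_preferring",
    "unclassified",
)


@dataclass
class SpecificityCall:
    """One per-protein classification with the contrasts supporting it."""

    protein_id: str
    call: str
    supporting: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (dataset, contrast label, logFC, adj_p)

    def __post_init__(self) -> None:
        if self.call not in CALL_LEVELS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.call != "unclassified" and not self.supporting:
            raise ValueError("a non-unclassified call must cite supporting contrasts")


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "protein_id": c.protein_id,
                "call": c.call,
                "supporting": ";".join(
                    f"{ds}:{lab}(logFC={fc:.3g},adj_p={q:.3g})"
                    for ds, lab, fc, q in c.supporting
                ),
                "datasets": ",".join(sorted({ds for ds, *_ in c.supporting})),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "call", "supporting", "datasets"])


@dataclass
class PrefilterResult:
    retained: list[str]
    matrix: IntensityMatrix  # pass-2 processed (normalized + imputed) matrix
    pass1_contrasts: dict[str, ContrastResult]
    fit: GroupFit | None = None
    prior: VariancePrior | None = None


def _seed_substreams(seed, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def prefilter_ub_enriched(
    raw_filtered_matrix: IntensityMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    seed=0,
    width: float = 0.3,
    shift: float = 1.8,
) -> PrefilterResult:
    """Two-pass prefilter for ubiquitin-enriched proteins (see module docs).

    ``raw_filtered_matrix`` must be linear scale, post valid-value filter and
    pre-normalization.  Returns the retained protein set, the re-processed
    pass-2 matrix, and the pass-1 bait-vs-control contrasts.
    """
    baits = [b for b in design.baits() if b != "bead_control"]
    if "bead_control" not in design.baits():
        raise ValueError("design has no bead_control group")
    sub1, sub2 = _seed_substreams(seed, 2)

    m1 = log2_median_normalize(raw_filtered_matrix)
    m1, _ = impute_downshift(m1, width=width, shift=shift, seed=sub1)
    fit1 = fit_groups(m1, design)
    prior1 = estimate_variance_prior(fit1.s2, fit1.df)
    contrasts = {}
    retained: set[str] = set()
    for bait in baits:
        res = moderated_t(fit1, prior1, bait, "bead_control")
        contrasts[res.label] = res
        hit = res.table.index[(res.table["adj_p"] < alpha) & (res.table["logFC"] > 0)]
        retained |= set(hit)
    retained_ordered = [p for p in raw_filtered_matrix.protein_ids if p in retained]
    if not retained_ordered:
        warnings.warn("prefilter retained no proteins; downstream stages will no-op")
        empty = raw_filtered_matrix.subset_proteins([])
        return PrefilterResult([], empty, contrasts)

    m2 = raw_filtered_matrix.subset_proteins(retained_ordered)
    m2 = log2_median_normalize(m2)
    m2, _ = impute_downshift(m2, width=width, shift=shift, seed=sub2)
    fit2 = fit_groups(m2, design)
    prior2 = estimate_variance_prior(fit2.s2, fit2.df)
    return PrefilterResult(retained_ordered, m2, contrasts, fit2, prior2)


def significant_across_baits(
    matrix: IntensityMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    fit: GroupFit | None = None,
    prior: VariancePrior | None = None,
) -> tuple[list[str], ContrastResult]:
    """Moderated F across bait groups (bead control excluded), BH at alpha."""
    baits = [b for b in design.baits() if b != "bead_control"]
    if len(baits) < 2:
        raise ValueError("need at least 2 bait groups for the F test")
    if fit is None:
        fit = fit_groups(matrix, design)
    if prior is None:
        prior = estimate_variance_prior(fit.s2, fit.df)
    res = moderated_F(fit, prior, baits)
    sig = list(res.table.index[res.table["adj_p"] < alpha])
    return sig, res


def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Row z-scoring (mean 0, sd 1 across columns); constant rows dropped."""
    sd = frame.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropped {int((~keep).sum())} constant row(s) before z-scoring")
    sub = frame.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def cluster_profiles(
    matrix: IntensityMatrix, protein_ids: list[str], k: int, method: str = "complete"
) -> pd.Series:
    """Hierarchical clustering of z-scored profiles, Euclidean distance,
    tree cut at ``k`` clusters.  Returns cluster labels (1..k) per protein."""
    frame = matrix.subset_proteins(protein_ids).to_frame()
    z = zscore_rows(frame)
    if k > len(z):
        raise ValueError(f"k={k} exceeds the {len(z)} clusterable proteins")
    link = hierarchy.linkage(pdist(z.to_numpy(), metric="euclidean"), method=method)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=z.index, name="cluster")


def bait_profiles(fit: GroupFit, protein_ids=None, z_score: bool = True) -> pd.DataFrame:
    """Per-bait group-effect values per protein (fitted group means from the
    one-way layout), optionally z-scored per protein — the per-pulldown
    summary used for interactome correlation and heatmap-style exports."""
    frame = fit.mean_frame()
    if protein_ids is not None:
        frame = frame.loc[[p for p in protein_ids if p in frame.index]]
    return zscore_rows(frame) if z_score else frame


def interactome_correlation(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho between each bait of A and each bait of B over the common
    significant proteins (rows).  Requires >= 3 common proteins."""
    common = profiles_a.index.intersection(profiles_b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common proteins; need >= 3")
    a = profiles_a.loc[common]
    b = profiles_b.loc[common]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            out.loc[ca, cb] = spearmanr(a[ca], b[cb]).statistic
    return out


# ---------------------------------------------------------------------------
# classification rules (pure functions of contrast tables)


def _as_dataset_map(results) -> dict[str, ContrastResult]:
    if isinstance(results, ContrastResult):
        return {"dataset": results}
    return dict(results)


def _passes(row, alpha: float, fc_min: float, positive: bool) -> bool:
    if positive:
        return row["adj_p"] < alpha and row["logFC"] > fc_min
    return row["adj_p"] < alpha and row["logFC"] < -fc_min


def classify_linkage(results, alpha: float = 0.05) -> list[SpecificityCall]:
    """Linkage preference from the K48_Ub3 vs K63_Ub3 moderated t contrast.

    ``results`` is a ContrastResult or {dataset: ContrastResult}.  A protein is
    called when significant in >= 1 dataset with no dataset significant in the
    opposite direction.
    """
    res = _as_dataset_map(results)
    if not res:
        raise ValueError("missing required contrast: K48_Ub3_vs_K63_Ub3")
    proteins = sorted(set().union(*[set(r.table.index) for r in res.values()]))
    calls = []
    for pid in proteins:
        pos, neg = [], []
        for ds, r in res.items():
            if pid not in r.table.index:
                continue
            row = r.table.loc[pid]
            if _passes(row, alpha, 0.0, positive=True):
                pos.append((ds, r.label, float(row["logFC"]), float(row["adj_p"])))
            elif _passes(row, alpha, 0.0, positive=False):
                neg.append((ds, r.label, float(row["logFC"]), float(row["adj_p"])))
        if pos and not neg:
            calls.append(SpecificityCall(pid, "linkage_K48", pos))
        elif neg and not pos:
            calls.append(SpecificityCall(pid, "linkage_K63", neg))
        else:
            calls.append(SpecificityCall(pid, "unclassified"))
    return calls


LENGTH_FC_THRESHOLD = {"K48": 0.5, "K63": 0.0}


def classify_length(
    results_by_dataset: dict[str, dict[str, ContrastResult]],
    alpha: float = 0.05,
    fc_threshold: dict[str, float] | None = None,
) -> list[SpecificityCall]:
    """Chain-length preference from Ub3-vs-Ub2 contrasts per linkage.

    ``results_by_dataset`` maps dataset -> {linkage ("K48"/"K63") ->
    ContrastResult of <linkage>_Ub3 vs <linkage>_Ub2}.  Call requires
    significance (adj_p < alpha) in at least one dataset AND a fold change
    beyond the linkage threshold, in the same direction, in *every* dataset
    (> 0.5 for K48; sign consistency only for K63).  The mirrored rule with
    negative fold changes yields a Ub2 preference.  Conflicting calls across
    linkages are both reported.
    """
    fc_threshold = dict(LENGTH_FC_THRESHOLD, **(fc_threshold or {}))
    calls: list[SpecificityCall] = []
    linkages = sorted({lk for per in results_by_dataset.values() for lk in per})
    if not linkages:
        raise ValueError("missing required contrast: no Ub3-vs-Ub2 results supplied")
    proteins = sorted(
        set().union(
            *[set(r.table.index) for per in results_by_dataset.values() for r in per.values()]
        )
    )
    for pid in proteins:
        per_protein: list[SpecificityCall] = []
        for linkage in linkages:
            thr = fc_threshold[linkage]
            rows = []
            for ds, per in results_by_dataset.items():
                if linkage not in per:
                    raise KeyError(
                        f"dataset {ds!r} lacks the {linkage} Ub3-vs-Ub2 contrast"
                    )
                if pid in per[linkage].table.index:
                    rows.append((ds, per[linkage].label, per[linkage].table.loc[pid]))
            if not rows:
                continue
            sig_any = any(row["adj_p"] < alpha for _, _, row in rows)
            up_all = all(row["logFC"] > thr for _, _, row in rows)
            down_all = all(row["logFC"] < -thr for _, _, row in rows)
            support = [
                (ds, lab, float(row["logFC"]), float(row["adj_p"])) for ds, lab, row in rows
            ]
            if sig_any and up_all:
                per_protein.append(SpecificityCall(pid, f"length_Ub3_{linkage}", support))
            elif sig_any and down_all:
                per_protein.append(SpecificityCall(pid, "length_Ub2_preferring", support))
        calls += per_protein if per_protein else [SpecificityCall(pid, "unclassified")]
    return calls


BRANCH_UB3_CONTRASTS = ("Br_Ub3_vs_K48_Ub3", "Br_Ub3_vs_K63_Ub3")
BRANCH_ALL_CONTRASTS = BRANCH_UB3_CONTRASTS + ("Br_Ub3_vs_K48_Ub2", "Br_Ub3_vs_K63_Ub2")


def classify_branch(
    results_by_dataset: dict[str, dict[str, ContrastResult]], alpha: float = 0.05
) -> list[SpecificityCall]:
    """Branch specificity from Br-Ub3-vs-homotypic contrasts.

    branch_specific: significant positive enrichment on the branched trimer
    over *both* homotypic Ub3 chains within at least one dataset.
    branch_specific_strict: all four Br-vs-homotypic (Ub2 and Ub3, both
    linkages) contrasts pass in every dataset supplied.
    homotypic_preferring: both Ub3 contrasts significant in the reverse
    direction within at least one dataset.  A protein triggering branch in one
    dataset and homotypic in another stays unclassified.
    """
    for ds, per in results_by_dataset.items():
        for lab in BRANCH_UB3_CONTRASTS:
            if lab not in per:
                raise KeyError(f"dataset {ds!r} lacks required contrast {lab}")
    proteins = sorted(
        set().union(
            *[set(r.table.index) for per in results_by_dataset.values() for r in per.values()]
        )
    )
    has_ub2 = all(
        all(lab in per for lab in BRANCH_ALL_CONTRASTS)
        for per in results_by_dataset.values()
    )
    calls = []
    for pid in proteins:
        branch_ds, homo_ds = [], []
        strict_every_ds = bool(results_by_dataset) and has_ub2
        support_all: list[tuple[str, str, float, float]] = []
        for ds, per in results_by_dataset.items():
            rows = {
                lab: per[lab].table.loc[pid]
                for lab in per
                if pid in per[lab].table.index
            }
            ub3 = [rows.get(lab) for lab in BRANCH_UB3_CONTRASTS]
            if any(r is None for r in ub3):
                strict_every_ds = False
                continue
            if all(_passes(r, alpha, 0.0, positive=True) for r in ub3):
                branch_ds.append(ds)
                support_all += [
                    (ds, lab, float(rows[lab]["logFC"]), float(rows[lab]["adj_p"]))
                    for lab in BRANCH_UB3_CONTRASTS
                ]
            if all(_passes(r, alpha, 0.0, positive=False) for r in ub3):
                homo_ds.append(ds)
                support_all += [
                    (ds, lab, float(rows[lab]["logFC"]), float(rows[lab]["adj_p"]))
                    for lab in BRANCH_UB3_CONTRASTS
                ]
            if has_ub2:
                all4 = [rows.get(lab) for lab in BRANCH_ALL_CONTRASTS]
                if any(r is None for r in all4) or not all(
                    _passes(r, alpha, 0.0, positive=True) for r in all4
                ):
                    strict_every_ds = False
        if branch_ds and homo_ds:
            calls.append(SpecificityCall(pid, "unclassified"))
        elif strict_every_ds and branch_ds:
            strict_support = [
                (ds, per[lab].label, float(per[lab].table.loc[pid]["logFC"]),
                 float(per[lab].table.loc[pid]["adj_p"]))
                for ds, per in results_by_dataset.items()
                for lab in BRANCH_ALL_CONTRASTS
            ]
            calls.append(SpecificityCall(pid, "branch_specific_strict", strict_support))
        elif branch_ds:
            calls.append(SpecificityCall(pid, "branch_specific", support_all))
        elif homo_ds:
            calls.append(SpecificityCall(pid, "homotypic_preferring", support_all))
        else:
            calls.append(SpecificityCall(pid, "unclassified"))
    return calls
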