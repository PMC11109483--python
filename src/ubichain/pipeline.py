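"""End-to-end orchestration: preprocess -> prefilter -> statistics ->
classification -> enrichment, over one or more datasets, with a structured
summary report.  Stage outputs written to disk are sufficient to resume any
later stage without recomputation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from .io import (
    IntensityMatrix,
    ProteinRecord,
    SampleDesign,
    check_design_matches_matrix,
    config_hash,
    read_design,
    read_protein_table,
)
from .modstats import ContrastResult, moderated_t
from .preprocess import PreprocessReport, run_preprocess
from .simulate import (
    PRIMARY_CALL,
    SimConfig,
    TruthLabels,
    implied_calls,
    simulate_study,
)
from .specificity import (
    PrefilterResult,
    bait_profiles,
    calls_to_frame,
    classify_branch,
    classify_length,
    classify_linkage,
    cluster_profiles,
    interactome_correlation,
    prefilter_ub_enriched,
    significant_across_baits,
)

CLASSIFICATION_CALLS = (
    "linkage_K48",
    "linkage_K63",
    "length_Ub3_K48",
    "length_Ub3_K63",
    "length_Ub2_preferring",
    "branch_specific",
    "branch_specific_strict",
    "homotypic_preferring",
)


@dataclass
class RunConfig:
    """Declarative run configuration (simulation or file inputs)."""

    sim: SimConfig | None = None
    datasets: tuple[str, ...] = ("CAA", "NEM")
    inputs: dict[str, dict[str, str]] = field(default_factory=dict)
    # dataset -> {"protein_table": path, "design": path}
    alpha: float = 0.05
    n_clusters: int = 4
    min_valid: int = 3
    impute_width: float = 0.3
    impute_shift: float = 1.8
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        sim = cfg.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        datasets = tuple(cfg.pop("datasets", ("CAA", "NEM")))
        inputs = cfg.pop("inputs", {})
        for ds, paths in inputs.items():
            for key in ("protein_table", "design"):
                if key not in paths:
                    raise ValueError(f"config inputs[{ds!r}] lacks field {key!r}")
        known = {"alpha", "n_clusters", "min_valid", "impute_width", "impute_shift", "seed"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config fields {sorted(unknown)}")
        return cls(sim=sim, datasets=datasets, inputs=inputs, **cfg)

    def to_dict(self) -> dict:
        d = {
            "datasets": list(self.datasets),
            "alpha": self.alpha,
            "n_clusters": self.n_clusters,
            "min_valid": self.min_valid,
            "impute_width": self.impute_width,
            "impute_shift": self.impute_shift,
            "seed": self.seed,
        }
        if self.sim is not None:
            d["sim"] = {
                "n_proteins": self.sim.n_proteins,
                "seed": self.sim.seed,
                "rep_sd": self.sim.rep_sd,
            }
        if self.inputs:
            d["inputs"] = self.inputs
        return d


@dataclass
class DatasetResult:
    dataset: str
    preprocess: PreprocessReport
    prefilter: PrefilterResult
    f_significant: list[str]
    f_result: ContrastResult
    contrasts: dict[str, ContrastResult]
    clusters: pd.Series | None


@dataclass
class Report:
    per_dataset: dict[str, DatasetResult]
    calls: pd.DataFrame
    correlation: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    truth: TruthLabels | None
    summary: str
    config_hash: str


def _load_or_simulate(config: RunConfig):
    if config.inputs:
        data, truth = {}, None
        for ds in config.datasets:
            if ds not in config.inputs:
                raise ValueError(f"config lacks inputs for dataset {ds!r}")
            paths = config.inputs[ds]
            matrix, records = read_protein_table(paths["protein_table"])
            design = read_design(paths["design"])
            check_design_matches_matrix(design, matrix)
            data[ds] = (matrix, design, records)
        return data, truth
    if config.sim is None:
        raise ValueError("config must provide either sim parameters or inputs")
    sim = config.sim
    if sim.seed != config.seed:
        sim = SimConfig(**{**sim.__dict__, "seed": config.seed})
    return simulate_study(sim, config.datasets)


def _pairwise_contrasts(pf: PrefilterResult, design: SampleDesign) -> dict[str, ContrastResult]:
    """All pairwise moderated-t contrasts the classification rules consume."""
    baits = set(design.baits())
    wanted = [
        ("K48_Ub3", "K63_Ub3"),
        ("K48_Ub3", "K48_Ub2"),
        ("K63_Ub3", "K63_Ub2"),
        ("Br_Ub3", "K48_Ub3"),
        ("Br_Ub3", "K63_Ub3"),
        ("Br_Ub3", "K48_Ub2"),
        ("Br_Ub3", "K63_Ub2"),
    ]
    out = {}
    for a, b in wanted:
        if a in baits and b in baits:
            res = moderated_t(pf.fit, pf.prior, a, b)
            out[res.label] = res
    return out


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> Report:
    """Execute the full analysis; optionally write all stage outputs.

    Deterministic given the config (identical config and seed reproduce
    byte-identical tables).
    """
    data, truth = _load_or_simulate(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.datasets))
    per_dataset: dict[str, DatasetResult] = {}
    for ds_seed, ds in zip(seeds, config.datasets):
        matrix, design, records = data[ds]
        sub_pre, sub_filt = ds_seed.spawn(2)
        processed, raw_filtered, imputed, pre_report = run_preprocess(
            matrix, records, design,
            min_valid=config.min_valid,
            width=config.impute_width, shift=config.impute_shift, seed=sub_pre,
        )
        pf = prefilter_ub_enriched(
            raw_filtered, design, alpha=config.alpha, seed=sub_filt,
            width=config.impute_width, shift=config.impute_shift,
        )
        if pf.retained:
            f_sig, f_res = significant_across_baits(
                pf.matrix, design, alpha=config.alpha, fit=pf.fit, prior=pf.prior
            )
            contrasts = _pairwise_contrasts(pf, design)
            clusters = None
            if len(f_sig) >= config.n_clusters:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clusters = cluster_profiles(pf.matrix, f_sig, config.n_clusters)
        else:
            f_sig, f_res, contrasts, clusters = [], None, {}, None
        per_dataset[ds] = DatasetResult(
            ds, pre_report, pf, f_sig, f_res, contrasts, clusters
        )

    calls = _classify_all(per_dataset, config.alpha)
    correlation = _between_dataset_correlation(per_dataset)
    enrichment_table = _truth_enrichment(per_dataset, truth) if truth is not None else None
    summary = _summarize(config, per_dataset, calls, enrichment_table)
    report = Report(
        per_dataset=per_dataset,
        calls=calls,
        correlation=correlation,
        enrichment=enrichment_table,
        truth=truth,
        summary=summary,
        config_hash=config_hash(config.to_dict()),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _classify_all(per_dataset: dict[str, DatasetResult], alpha: float) -> pd.DataFrame:
    linkage_in = {
        ds: r.contrasts["K48_Ub3_vs_K63_Ub3"]
        for ds, r in per_dataset.items()
        if "K48_Ub3_vs_K63_Ub3" in r.contrasts
    }
    length_in = {}
    branch_in = {}
    for ds, r in per_dataset.items():
        per_linkage = {}
        if "K48_Ub3_vs_K48_Ub2" in r.contrasts:
            per_linkage["K48"] = r.contrasts["K48_Ub3_vs_K48_Ub2"]
        if "K63_Ub3_vs_K63_Ub2" in r.contrasts:
            per_linkage["K63"] = r.contrasts["K63_Ub3_vs_K63_Ub2"]
        if per_linkage:
            length_in[ds] = per_linkage
        br = {lab: c for lab, c in r.contrasts.items() if lab.startswith("Br_Ub3_vs_")}
        if {"Br_Ub3_vs_K48_Ub3", "Br_Ub3_vs_K63_Ub3"} <= set(br):
            branch_in[ds] = br

    all_calls = []
    if linkage_in:
        all_calls += classify_linkage(linkage_in, alpha)
    if length_in:
        all_calls += classify_length(length_in, alpha)
    if branch_in:
        all_calls += classify_branch(branch_in, alpha)
    real = [c for c in all_calls if c.call != "unclassified"]
    called = {c.protein_id for c in real}
    frame = calls_to_frame(real)

    # prefiltered proteins with no specific call are still Ub-enriched binders
    prefiltered = sorted(
        set().union(*[set(r.prefilter.retained) for r in per_dataset.values()])
    )
    leftover = [p for p in prefiltered if p not in called]
    if leftover:
        extra = pd.DataFrame(
            {
                "protein_id": leftover,
                "call": "ub_enriched_only",
                "supporting": "",
                "datasets": "",
            }
        )
        frame = pd.concat([frame, extra], ignore_index=True)
    return frame.sort_values(["protein_id", "call"]).reset_index(drop=True)


def _between_dataset_correlation(per_dataset) -> pd.DataFrame | None:
    names = list(per_dataset)
    if len(names) < 2:
        return None
    a, b = per_dataset[names[0]], per_dataset[names[1]]
    if a.prefilter.fit is None or b.prefilter.fit is None:
        return None
    common = sorted(set(a.f_significant) & set(b.f_significant))
    if len(common) < 3:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = bait_profiles(a.prefilter.fit, common)
        pb = bait_profiles(b.prefilter.fit, common)
    return interactome_correlation(pa, pb)


def _truth_enrichment(per_dataset, truth: TruthLabels) -> pd.DataFrame:
    """Fisher enrichment of planted interactors in each prefiltered set."""
    expected = {
        p
        for p, c in zip(truth.protein_ids, truth.classes)
        if c not in ("background", "bead_binder")
    }
    rows = []
    for ds, r in per_dataset.items():
        n_all = len(truth.protein_ids)
        k_all = len(expected)
        retained = set(r.prefilter.retained)
        k_in = len(retained & expected)
        n_in = len(retained)
        if n_in == 0:
            continue
        odds, p = enr.fisher_ubbp_enrichment(k_in, n_in, k_all, n_all)
        factor = enr.enrichment_factor(k_in, n_in, k_all, n_all)
        rows.append(
            {
                "dataset": ds,
                "k_in": k_in,
                "n_in": n_in,
                "k_all": k_all,
                "n_all": n_all,
                "odds_ratio": odds,
                "p": p,
                "enrichment_factor": factor,
            }
        )
    return pd.DataFrame(rows)


def score_recovery(
    calls: pd.DataFrame, truth: TruthLabels
) -> tuple[dict[str, float], float]:
    """Per-class sensitivity and overall false-discovery proportion vs truth.

    Sensitivity: fraction of planted members of each specificity class that
    received the class's headline call.  FDP: among all emitted
    linkage/length/branch calls, the fraction not supported by the protein's
    planted class (a length-dependent K48 binder legitimately supports both a
    length and a linkage call).
    """
    by_protein: dict[str, set[str]] = {}
    for _, row in calls.iterrows():
        by_protein.setdefault(row["protein_id"], set()).add(row["call"])
    implied = {
        pid: implied_calls(truth.delta.loc[pid].to_dict()) for pid in truth.protein_ids
    }
    sensitivity = {}
    for cls, want in PRIMARY_CALL.items():
        members = truth.members(cls)
        ok_calls = {want, "branch_specific_strict"} if cls == "branch_specific" else {want}
        hit = sum(1 for p in members if by_protein.get(p, set()) & ok_calls)
        sensitivity[cls] = hit / len(members) if members else float("nan")
    n_calls = 0
    n_false = 0
    for pid, pcalls in by_protein.items():
        for call in pcalls:
            if call not in CLASSIFICATION_CALLS:
                continue
            n_calls += 1
            if call not in implied.get(pid, frozenset()):
                n_false += 1
    fdp = n_false / n_calls if n_calls else 0.0
    return sensitivity, fdp


def _summarize(config, per_dataset, calls, enrichment_table) -> str:
    lines = [
        "ubiquitin chain interactome analysis - run summary",
        f"config hash: {config_hash(config.to_dict())}  seed: {config.seed}",
        "",
    ]
    for ds, r in per_dataset.items():
        pre = r.preprocess
        lines += [
            f"[{ds}]",
            f"  input rows:            {pre.n_input}",
            f"  flagged rows removed:  {pre.n_flagged}",
            f"  dropout samples:       {len(pre.dropout_samples)}",
            f"  after valid-value:     {pre.n_after_valid_filter}",
            f"  prefiltered (Ub-enr.): {len(r.prefilter.retained)}",
            f"  F-significant:         {len(r.f_significant)}",
        ]
        if r.clusters is not None:
            counts = r.clusters.value_counts().sort_index()
            lines.append(
                "  cluster sizes:         "
                + ", ".join(f"{k}:{v}" for k, v in counts.items())
            )
        lines.append("")
    call_counts = calls["call"].value_counts()
    lines.append("classification calls:")
    for call, n in call_counts.items():
        lines.append(f"  {call:24s} {n}")
    if enrichment_table is not None and len(enrichment_table):
        lines.append("")
        lines.append("planted-interactor enrichment in prefiltered sets:")
        for _, row in enrichment_table.iterrows():
            lines.append(
                f"  {row['dataset']}: {row['k_in']}/{row['n_in']} vs "
                f"{row['k_all']}/{row['n_all']}  odds={row['odds_ratio']:.2f}  "
                f"p={row['p']:.3g}  factor={row['enrichment_factor']:.2f}"
            )
    return "\n".join(lines) + "\n"


def write_report(report: Report, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds, r in report.per_dataset.items():
        if r.f_result is not None:
            r.f_result.table.to_csv(out / f"{ds}_moderated_F.tsv", sep="\t")
        for lab, c in r.contrasts.items():
            c.table.to_csv(out / f"{ds}_{lab}.tsv", sep="\t")
        for lab, c in r.prefilter.pass1_contrasts.items():
            c.table.to_csv(out / f"{ds}_prefilter_{lab}.tsv", sep="\t")
        pd.Series(r.prefilter.retained, name="protein_id").to_csv(
            out / f"{ds}_prefiltered_proteins.tsv", sep="\t", index=False
        )
        if r.clusters is not None:
            r.clusters.to_csv(out / f"{ds}_clusters.tsv", sep="\t")
            for k, members in r.clusters.groupby(r.clusters):
                (out / f"{ds}_cluster{k}_genes.txt").write_text(
                    "\n".join(members.index) + "\n"
                )
    report.calls.to_csv(out / "specificity_calls.tsv", sep="\t", index=False)
    if report.correlation is not None:
        report.correlation.to_csv(out / "interactome_correlation.tsv", sep="\t")
    if report.enrichment is not None:
        report.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if report.truth is not None:
        from .simulate import truth_to_frame

        truth_to_frame(report.truth).to_csv(out / "truth_labels.tsv", sep="\t")
    (out / "summary.txt").write_text(report.summary)
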