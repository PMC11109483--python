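"""Synthetic pulldown and SPR data with known ground truth.

The interactome generator emulates the study design the analysis assumes:
quadruplicate streptavidin pulldowns for a bead-only control and a panel of
ubiquitin chain baits (mono-Ub, K48/K63 Ub2/Ub3, K48/K63-branched Ub3), with
planted interactor classes.  Log2 intensities are

    x_{g,s} = b_g + delta_{g, bait(s)} + eps,   eps ~ Normal(0, sigma_rep^2)

exponentiated to a linear iBAQ-like scale, then thinned by intensity-dependent
(MNAR) dropout: a cell at log2 intensity x is masked with probability
1 / (1 + exp(beta * (x - gamma))), i.e. low-abundance measurements vanish
preferentially — the regime that downshift imputation assumes.

The SPR side simulates 1:1 Langmuir binding: full sensorgrams with
association/dissociation kinetics, and equilibrium series on the hyperbola
Req = C*Rmax/(KD + C) plus Gaussian read noise.

Because every planted class and effect size is retained in ``TruthLabels``,
the generator doubles as the oracle for recovery scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntensityMatrix, ProteinRecord, SampleDesign
from .spr import Sensorgram, SteadyStateSeries, steady_state_response

CLASS_NAMES = (
    "background",
    "bead_binder",
    "pan_ub",
    "K48_specific",
    "K63_specific",
    "length_dependent_K48",
    "length_dependent_K63",
    "branch_specific",
    "branch_excluded",
)

DEFAULT_PROPORTIONS = {
    "background": 0.70,
    "bead_binder": 0.05,
    "pan_ub": 0.05,
    "K48_specific": 0.05,
    "K63_specific": 0.05,
    "length_dependent_K48": 0.025,
    "length_dependent_K63": 0.025,
    "branch_specific": 0.025,
    "branch_excluded": 0.025,
}

DEFAULT_BAITS = (
    "bead_control",
    "mono_Ub",
    "K48_Ub2",
    "K48_Ub3",
    "K63_Ub2",
    "K63_Ub3",
    "Br_Ub3",
)

#: Per-class log2 enrichment over baseline, per bait.  A preferred bait gets
#: delta = 3 (an 8-fold pull), length-dependent classes add +1.5 on Ub3 over
#: Ub2 of their linkage, branch-specific binders see the branched trimer at 3
#: with homotypic trimers at 1, branch-excluded binders the reverse, and bead
#: binders stick to everything (control included) at 2.  These separations are
#: comfortably detectable at n = 4 with sigma_rep ~ 0.4.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "background": {},
    "bead_binder": {b: 2.0 for b in DEFAULT_BAITS},
    "pan_ub": {b: 3.0 for b in DEFAULT_BAITS if b != "bead_control"},
    "K48_specific": {"K48_Ub2": 3.0, "K48_Ub3": 3.0, "Br_Ub3": 1.5},
    "K63_specific": {"K63_Ub2": 3.0, "K63_Ub3": 3.0, "Br_Ub3": 1.5},
    "length_dependent_K48": {"K48_Ub2": 3.0, "K48_Ub3": 4.5, "Br_Ub3": 1.5},
    "length_dependent_K63": {"K63_Ub2": 3.0, "K63_Ub3": 4.5, "Br_Ub3": 1.5},
    "branch_specific": {"Br_Ub3": 3.0, "K48_Ub3": 1.0, "K63_Ub3": 1.0},
    "branch_excluded": {
        "K48_Ub2": 3.0, "K48_Ub3": 3.0, "K63_Ub2": 3.0, "K63_Ub3": 3.0, "Br_Ub3": 1.0
    },
}

def implied_calls(delta: dict[str, float], k48_length_fc: float = 0.5) -> frozenset[str]:
    """Calls a protein's *true* effect vector legitimately supports.

    The classification rules are applied to the planted per-bait log2 effects
    (the population fold changes), so a call on a protein is a true discovery
    exactly when its planted pattern satisfies the rule's direction and
    threshold.  E.g. a branch-specific binder planted with homotypic Ub3 at
    +1 over Ub2 genuinely supports a Ub3-length call too.
    """
    d = {b: float(delta.get(b, 0.0)) for b in set(delta)}
    g = d.get
    out: set[str] = set()
    if g("K48_Ub3", 0) > g("K63_Ub3", 0):
        out.add("linkage_K48")
    elif g("K48_Ub3", 0) < g("K63_Ub3", 0):
        out.add("linkage_K63")
    k48_len = g("K48_Ub3", 0) - g("K48_Ub2", 0)
    k63_len = g("K63_Ub3", 0) - g("K63_Ub2", 0)
    if k48_len > k48_length_fc:
        out.add("length_Ub3_K48")
    if k63_len > 0:
        out.add("length_Ub3_K63")
    if k48_len < -k48_length_fc or k63_len < 0:
        out.add("length_Ub2_preferring")
    br48 = g("Br_Ub3", 0) - g("K48_Ub3", 0)
    br63 = g("Br_Ub3", 0) - g("K63_Ub3", 0)
    if br48 > 0 and br63 > 0:
        out.add("branch_specific")
        if g("Br_Ub3", 0) > g("K48_Ub2", 0) and g("Br_Ub3", 0) > g("K63_Ub2", 0):
            out.add("branch_specific_strict")
    if br48 < 0 and br63 < 0:
        out.add("homotypic_preferring")
    if any(v > 0 for b, v in d.items() if b != "bead_control"):
        out.add("ub_enriched_only")
    return frozenset(out)

#: The headline call each planted class should receive (sensitivity target).
PRIMARY_CALL: dict[str, str] = {
    "K48_specific": "linkage_K48",
    "K63_specific": "linkage_K63",
    "length_dependent_K48": "length_Ub3_K48",
    "length_dependent_K63": "length_Ub3_K63",
    "branch_specific": "branch_specific",
    "branch_excluded": "homotypic_preferring",
}


@dataclass
class SimConfig:
    """Study-design parameters for the interactome simulator."""

    n_proteins: int = 2000
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    baits: tuple[str, ...] = DEFAULT_BAITS
    n_replicates: int = 4
    baseline_mean: float = 25.0  # log2 iBAQ
    baseline_sd: float = 2.0
    rep_sd: float = 0.4  # replicate noise, log2 units
    mnar_mid: float = 22.0  # gamma: log2 intensity of 50% dropout
    mnar_slope: float = 1.0  # beta: steepness of the dropout sigmoid
    mnar: bool = True
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    frac_reverse: float = 0.01  # decoy rows appended to exercise flag filtering
    frac_contaminant: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.proportions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown planted classes {sorted(unknown)}")
        if self.baseline_sd <= 0 or self.rep_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if "bead_control" not in self.baits:
            raise ValueError("the bait panel must include bead_control")


@dataclass
class TruthLabels:
    """Planted ground truth: class, baseline and per-bait effect per protein."""

    protein_ids: list[str]
    classes: np.ndarray  # str per protein
    baseline: np.ndarray  # log2
    delta: pd.DataFrame  # protein x bait log2 effect

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.classes, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def members(self, cls: str) -> list[str]:
        return [p for p, c in zip(self.protein_ids, self.classes) if c == cls]

    def class_of(self) -> dict[str, str]:
        return dict(zip(self.protein_ids, self.classes.tolist()))


def _class_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment; exact for proportions like 0.7 * 2000."""
    names = [c for c in CLASS_NAMES if c in proportions]
    raw = np.array([proportions[c] * n for c in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def draw_truth(config: SimConfig, rng: np.random.Generator) -> TruthLabels:
    counts = _class_counts(config.n_proteins, config.proportions)
    classes = np.concatenate([[c] * k for c, k in counts.items()])
    rng.shuffle(classes)
    ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    delta = pd.DataFrame(0.0, index=ids, columns=list(config.baits))
    for i, cls in enumerate(classes):
        for bait, d in config.effects.get(cls, {}).items():
            if bait in delta.columns:
                delta.iloc[i, delta.columns.get_loc(bait)] = d
    return TruthLabels(ids, np.asarray(classes), baseline, delta)


def apply_mnar_dropout(
    matrix: IntensityMatrix, gamma: float, beta: float, seed
) -> IntensityMatrix:
    """Mask each present cell independently with P = 1/(1+exp(beta*(x-gamma))).

    ``matrix`` must be on the log2 scale; the dropout probability decreases in
    intensity, emulating detection-limit censoring.  ``beta`` must be >= 0
    (negative values would preferentially erase high intensities).
    """
    if matrix.scale != "log2":
        raise ValueError("MNAR dropout operates on the log2 scale")
    if beta < 0:
        raise ValueError("mnar slope beta must be nonnegative")
    rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(beta * (matrix.values - gamma)))
    p_miss = np.where(matrix.missing, 0.0, p_miss)
    drop = rng.random(matrix.values.shape) < p_miss
    new_missing = matrix.missing | drop
    return IntensityMatrix(
        list(matrix.protein_ids),
        list(matrix.sample_ids),
        np.where(new_missing, np.nan, matrix.values),
        new_missing,
        "log2",
    )


def realize_dataset(
    truth: TruthLabels, config: SimConfig, dataset: str, rng: np.random.Generator
) -> tuple[IntensityMatrix, SampleDesign, list[ProteinRecord]]:
    """One dataset realization (noise + missingness) of a shared truth."""
    sample_ids, baits, reps = [], [], []
    for bait in config.baits:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{dataset}_{bait}_{r}")
            baits.append(bait)
            reps.append(r)
    design = SampleDesign(
        pd.DataFrame(
            {"sample_id": sample_ids, "bait": baits, "replicate": reps, "dataset": dataset}
        )
    )
    effect = truth.delta.reindex(columns=baits, fill_value=0.0).to_numpy()
    x = (
        truth.baseline[:, None]
        + effect
        + rng.normal(0.0, config.rep_sd, size=(len(truth.protein_ids), len(sample_ids)))
    )
    log_matrix = IntensityMatrix(
        list(truth.protein_ids), sample_ids, x, np.zeros_like(x, dtype=bool), "log2"
    )
    if config.mnar:
        log_matrix = apply_mnar_dropout(
            log_matrix, config.mnar_mid, config.mnar_slope, rng.integers(2**31)
        )
    matrix = log_matrix.to_linear()
    records = [ProteinRecord(protein_id=p, gene=p) for p in truth.protein_ids]

    # decoy rows (reverse hits / contaminants) exercise flag filtering
    n_rev = int(round(config.frac_reverse * config.n_proteins))
    n_con = int(round(config.frac_contaminant * config.n_proteins))
    if n_rev or n_con:
        n_extra = n_rev + n_con
        xb = rng.normal(config.baseline_mean, config.baseline_sd, size=(n_extra, 1))
        xe = xb + rng.normal(0.0, config.rep_sd, size=(n_extra, len(sample_ids)))
        extra_ids = [f"REV{i:04d}" for i in range(n_rev)] + [
            f"CON{i:04d}" for i in range(n_con)
        ]
        extra = IntensityMatrix(
            extra_ids, sample_ids, np.exp2(xe), np.zeros_like(xe, dtype=bool), "linear"
        )
        matrix = IntensityMatrix(
            matrix.protein_ids + extra_ids,
            sample_ids,
            np.vstack([np.where(matrix.missing, 0.0, matrix.values), extra.values]),
            np.vstack([matrix.missing, extra.missing]),
            "linear",
        )
        # restore NaN at masked cells (constructor enforces it anyway)
        records += [
            ProteinRecord(protein_id=p, gene=p, reverse=p.startswith("REV"),
                          contaminant=p.startswith("CON"))
            for p in extra_ids
        ]
    return matrix, design, records


def simulate_interactome(
    config: SimConfig,
) -> tuple[IntensityMatrix, SampleDesign, list[ProteinRecord], TruthLabels]:
    """Simulate one pulldown dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    matrix, design, records = realize_dataset(truth, config, "SIM", rng)
    return matrix, design, records, truth


def simulate_study(
    config: SimConfig, datasets: tuple[str, ...] = ("CAA", "NEM")
) -> tuple[dict[str, tuple[IntensityMatrix, SampleDesign, list[ProteinRecord]]], TruthLabels]:
    """Simulate several datasets sharing one planted truth (biology), with
    independent noise and missingness per dataset — the two-inhibitor design."""
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    out = {}
    for ds in datasets:
        out[ds] = realize_dataset(truth, config, ds, rng)
    return out, truth


def truth_to_frame(truth: TruthLabels) -> pd.DataFrame:
    df = truth.delta.copy()
    df.insert(0, "planted_class", truth.classes)
    df.insert(1, "baseline_log2", truth.baseline)
    df.index.name = "protein_id"
    return df


def truth_from_frame(df: pd.DataFrame) -> TruthLabels:
    """Inverse of :func:`truth_to_frame` (index = protein_id)."""
    delta = df.drop(columns=["planted_class", "baseline_log2"])
    return TruthLabels(
        list(df.index),
        df["planted_class"].to_numpy(),
        df["baseline_log2"].to_numpy(dtype=float),
        delta,
    )


# ---------------------------------------------------------------------------
# SPR simulation


def default_concentration_grid() -> np.ndarray:
    """Two-fold dilution series, 13 points from ~0.061 to 250 uM."""
    return 250.0 / 2.0 ** np.arange(12, -1, -1)


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentrations,
    t_assoc: float = 120.0,
    t_dissoc: float = 120.0,
    noise_sd: float = 0.0,
    seed=0,
    dt: float = 0.1,
) -> list[Sensorgram]:
    """Multicycle 1:1-binding sensorgrams, one cycle per concentration.

    Association: R(t) = Req(C) * (1 - exp(-(kon*C + koff)*t)) with
    Req(C) = C*Rmax/(C + KD), KD = koff/kon.  Dissociation decays from the
    association end level with rate koff.  Gaussian noise is added pointwise.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and Rmax must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    rng = np.random.default_rng(seed)
    kd = koff / kon
    out = []
    time = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    for cycle, conc in enumerate(concentrations, start=1):
        req = steady_state_response(conc, kd, rmax)
        kobs = kon * conc + koff
        assoc = time <= t_assoc
        resp = np.empty_like(time)
        resp[assoc] = req * (1.0 - np.exp(-kobs * time[assoc]))
        r_end = req * (1.0 - np.exp(-kobs * t_assoc))
        resp[~assoc] = r_end * np.exp(-koff * (time[~assoc] - t_assoc))
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        out.append(
            Sensorgram(
                cycle=cycle,
                concentration=float(conc),
                time=time.copy(),
                response=resp,
                association_window=(0.0, t_assoc),
                dissociation_window=(t_assoc, t_assoc + t_dissoc),
            )
        )
    return out


def simulate_steady_state(
    kd: float,
    rmax: float,
    concentrations=None,
    noise_sd: float = 0.5,
    n_rep: int = 3,
    seed=0,
) -> list[SteadyStateSeries]:
    """Replicate equilibrium series on the binding hyperbola plus read noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("KD and Rmax must be positive")
    conc = default_concentration_grid() if concentrations is None else np.asarray(
        concentrations, dtype=float
    )
    rng = np.random.default_rng(seed)
    ideal = steady_state_response(conc, kd, rmax)
    out = []
    for rep in range(1, n_rep + 1):
        noise = rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else 0.0
        out.append(SteadyStateSeries(rep, conc.copy(), ideal + noise))
    return out
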