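"""Validation statistics: Fisher exact enrichment of expected ubiquitin
binders in filtered protein sets, enrichment factors against a reference
proteome, and set-overlap counts."""

from __future__ import annotations

from itertools import combinations

from scipy.stats import fisher_exact


def fisher_ubbp_enrichment(
    k_in: int, n_in: int, k_all: int, n_all: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher exact test of annotation enrichment in a filtered subset.

    ``k_in`` of ``n_in`` filtered proteins are annotated, against ``k_all`` of
    ``n_all`` total.  The 2x2 table uses disjoint categories — filtered versus
    not-filtered — so each protein is counted once:

        [[k_in, n_in - k_in], [k_all - k_in, (n_all - n_in) - (k_all - k_in)]]

    Returns (odds ratio, p).  Two-sided p is the exact hypergeometric sum of
    all outcome probabilities no larger than the observed one.
    """
    if not (0 <= k_in <= n_in <= n_all):
        raise ValueError("need 0 <= k_in <= n_in <= n_all")
    if not (k_in <= k_all <= n_all):
        raise ValueError("need k_in <= k_all <= n_all")
    k_out = k_all - k_in
    n_out = n_all - n_in
    if k_out > n_out:
        raise ValueError("annotated proteins outside the subset exceed its size")
    table = [[k_in, n_in - k_in], [k_out, n_out - k_out]]
    odds, p = fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def enrichment_factor(k_in: int, n_in: int, k_ref: int, n_ref: int) -> float:
    """Proportion ratio (k_in/n_in) / (k_ref/n_ref) versus a reference list."""
    if n_in <= 0 or n_ref <= 0:
        raise ValueError("set sizes must be positive")
    if k_ref <= 0:
        raise ValueError("reference count k_ref = 0 leaves the factor undefined")
    return (k_in / n_in) / (k_ref / n_ref)


def overlap_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Cardinality of every exclusive intersection region of the named sets.

    Keys are sorted tuples of the set names a region belongs to; e.g. for
    sets A and B the key ("A", "B") counts elements in both, ("A",) counts
    elements in A only.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*[sets[n] for n in inside])
            for n in names:
                if n not in inside:
                    region = region - sets[n]
            out[inside] = len(region)
    return out
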