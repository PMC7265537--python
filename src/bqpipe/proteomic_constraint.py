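"""Mutation-rate / genome-information-content relation and its inversions.

mu = k / (2 * Ne * s_bar * pi * P): the per-nucleotide mutation rate that
selection can maintain falls as effective population size, mean selection
coefficient, heterozygosity, or proteome size (the mutational target) grows.
k is a free proportionality constant with no calibrated default.
"""

from __future__ import annotations

__all__ = ["PARAMS", "mutation_rate", "solve_for"]

PARAMS = ("k", "Ne", "s_bar", "pi", "P")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def mutation_rate(k: float, Ne: float, s_bar: float, pi: float, P: float) -> float:
    """mu = k / (2 * Ne * s_bar * pi * P); strictly positive inputs required."""
    _check_positive(k=k, Ne=Ne, s_bar=s_bar, pi=pi, P=P)
    return k / (2.0 * Ne * s_bar * pi * P)


def solve_for(target: str, mu: float, **params: float) -> float:
    """Invert the relation for any single parameter, given mu and the rest.

    Substituting the result back into :func:`mutation_rate` reproduces mu to
    machine precision (the relation is a pure product).
    """
    if target not in PARAMS:
        raise ValueError(f"unknown target {target!r}; choose from {PARAMS}")
    _check_positive(mu=mu)
    needed = tuple(p for p in PARAMS if p != target)
    if set(params) != set(needed):
        raise ValueError(
            f"solving for {target} requires exactly the other parameters {needed}"
        )
    known = {p: params[p] for p in needed}
    _check_positive(**known)
    denom_terms = {p: v for p, v in known.items() if p != "k"}
    prod = 1.0
    for v in denom_terms.values():
        prod *= v
    if target == "k":
        return mu * 2.0 * prod
    # mu = k / (2 * prod * target)  =>  target = k / (2 * mu * prod)
    return known["k"] / (2.0 * mu * prod)
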