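"""Substitution calculus over the standard genetic code.

Which base substitutions turn a sense codon into a premature stop codon?
A prime editor can write arbitrary substitutions, so every sense codon is
at most three substitutions from each of TAA/TAG/TGA.  A cytosine base
editor (CBE) deaminates one strand only, so its routes to a stop are
restricted to all-C→T edits on the coding strand or all-G→A edits on the
coding strand (C→T on the template strand); only codons of Gln, Arg and
Trp have such a route.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from Bio.Data.CodonTable import unambiguous_dna_by_id

STOP_CODONS: tuple[str, str, str] = ("TAA", "TAG", "TGA")
_BASES = frozenset("ACGT")

#: codon -> one-letter amino acid, standard code (translation table 1)
CODON_TO_AA: dict[str, str] = dict(unambiguous_dna_by_id[1].forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

ALL_AMINO_ACIDS: frozenset[str] = frozenset(CODON_TO_AA.values())


class NotASenseCodonError(ValueError):
    """Raised when an operation requires a sense codon but got a stop/invalid one."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _BASES:
        raise NotASenseCodonError(f"invalid codon {codon!r}: need 3 bases over ACGT")
    if codon in STOP_CODONS:
        raise NotASenseCodonError(f"{codon} is already a stop codon")
    return codon


@dataclass(frozen=True)
class SubstitutionPlan:
    """A set of per-position base changes converting one codon into a stop codon.

    Positions are 0-based offsets within the codon.  Applying the plan to
    the source codon must yield ``product``, one of TAA/TAG/TGA.
    """

    positions: tuple[int, ...]
    from_bases: tuple[str, ...]
    to_bases: tuple[str, ...]
    product: str

    @property
    def n_subs(self) -> int:
        return len(self.positions)

    def apply(self, codon: str) -> str:
        out = list(codon.upper())
        for pos, src, dst in zip(self.positions, self.from_bases, self.to_bases):
            if out[pos] != src:
                raise ValueError(
                    f"plan expects {src} at codon position {pos}, found {out[pos]}"
                )
            out[pos] = dst
        return "".join(out)

    def __str__(self) -> str:  # e.g. "CGA>TGA (C1T)"
        edits = ",".join(
            f"{s}{p + 1}{d}"
            for p, s, d in zip(self.positions, self.from_bases, self.to_bases)
        )
        return f">{self.product} ({edits})"


def _plan_sort_key(plan: SubstitutionPlan) -> tuple[int, int]:
    return (plan.n_subs, STOP_CODONS.index(plan.product))


def _plan_to(codon: str, stop: str) -> SubstitutionPlan | None:
    """The unique plan converting ``codon`` into ``stop`` (None if identical)."""
    diff = tuple(i for i in range(3) if codon[i] != stop[i])
    if not diff:
        return None
    return SubstitutionPlan(
        positions=diff,
        from_bases=tuple(codon[i] for i in diff),
        to_bases=tuple(stop[i] for i in diff),
        product=stop,
    )


def stops_reachable(codon: str, max_subs: int = 3) -> list[SubstitutionPlan]:
    """Every plan converting a sense codon into a stop with <= ``max_subs`` changes.

    For a fixed stop codon the substitution set is exactly the positions that
    differ, so at most three plans exist.  Sorted by substitution count, then
    by product in the fixed order TAA < TAG < TGA.
    """
    codon = _check_sense(codon)
    if not 1 <= max_subs <= 3:
        raise ValueError("max_subs must be in 1..3")
    plans = []
    for stop in STOP_CODONS:
        plan = _plan_to(codon, stop)
        if plan is not None and plan.n_subs <= max_subs:
            plans.append(plan)
    return sorted(plans, key=_plan_sort_key)


def cbe_stop_routes(codon: str) -> list[SubstitutionPlan]:
    """Strand-pure CBE routes to a stop: all C→T, or all G→A, within one codon.

    A single CBE exposure deaminates cytosines on one strand, so a route
    mixing coding-strand C→T with template-strand C→T (coding G→A) is not
    a single-editor outcome and is excluded.
    """
    codon = _check_sense(codon)
    routes: list[SubstitutionPlan] = []
    for src, dst in (("C", "T"), ("G", "A")):
        editable = [i for i in range(3) if codon[i] == src]
        for r in range(1, len(editable) + 1):
            for subset in combinations(editable, r):
                product = "".join(
                    dst if i in subset else codon[i] for i in range(3)
                )
                if product in STOP_CODONS:
                    routes.append(
                        SubstitutionPlan(
                            positions=tuple(subset),
                            from_bases=tuple(src for _ in subset),
                            to_bases=tuple(dst for _ in subset),
                            product=product,
                        )
                    )
    return sorted(routes, key=_plan_sort_key)


def amino_acids_stop_reachable(chemistry: str) -> set[str]:
    """One-letter symbols of amino acids with >=1 codon convertible to a stop.

    ``chemistry`` is "PE" (unrestricted substitutions, <=3 per codon) or
    "CBE" (strand-pure C→T / G→A routes only).
    """
    chem = chemistry.upper()
    if chem == "PE":
        finder = lambda c: stops_reachable(c, max_subs=3)  # noqa: E731
    elif chem == "CBE":
        finder = cbe_stop_routes
    else:
        raise ValueError(f"unknown chemistry {chemistry!r}: expected PE or CBE")
    return {CODON_TO_AA[c] for c in SENSE_CODONS if finder(c)}


def min_plan(
    codon: str, forced_stop: str | None = None, max_subs: int = 3
) -> SubstitutionPlan:
    """The preferred stop-conversion plan for a codon.

    With ``forced_stop`` the unique plan to that stop codon is returned.
    Otherwise the first plan under the ``stops_reachable`` ordering: fewest
    substitutions, ties broken TAA < TAG < TGA (a fixed deterministic policy;
    the choice of stop codon is biologically arbitrary).
    """
    codon = _check_sense(codon)
    if forced_stop is not None:
        forced_stop = forced_stop.upper()
        if forced_stop not in STOP_CODONS:
            raise ValueError(f"forced_stop must be one of {STOP_CODONS}")
        plan = _plan_to(codon, forced_stop)
        if plan is None or plan.n_subs > max_subs:
            raise ValueError(
                f"no plan from {codon} to {forced_stop} within {max_subs} substitutions"
            )
        return plan
    plans = stops_reachable(codon, max_subs=max_subs)
    if not plans:
        raise ValueError(f"no stop reachable from {codon} within {max_subs} substitutions")
    return plans[0]
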