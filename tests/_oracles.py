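"""Tiny independent oracles used only by the tests.

These enumerate exhaustively and share no code with the package's own
implementations (the package's naive scanners live in pestop.bruteforce and
are themselves cross-checked here against the optimized scanners).
"""

from itertools import product

STOPS = ("TAA", "TAG", "TGA")

_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, repeat=3)):
    _CODE[_b1 + _b2 + _b3] = _AAS[_i]

SENSE = sorted(c for c, aa in _CODE.items() if aa != "*")


def enumerate_stop_plans(codon: str, max_subs: int = 3) -> set[tuple]:
    """All substitution patterns (over the full 4^3 codon space) turning
    ``codon`` into a stop with 1..max_subs changes."""
    out = set()
    for alt in product("ACGT", repeat=3):
        new = "".join(alt)
        if new not in STOPS:
            continue
        positions = tuple(i for i in range(3) if new[i] != codon[i])
        if 1 <= len(positions) <= max_subs:
            out.add(
                (
                    positions,
                    tuple(codon[i] for i in positions),
                    tuple(new[i] for i in positions),
                    new,
                )
            )
    return out


def enumerate_cbe_routes(codon: str) -> set[tuple]:
    """Strand-pure C->T / G->A substitution subsets reaching a stop."""
    out = set()
    for src, dst in (("C", "T"), ("G", "A")):
        idx = [i for i in range(3) if codon[i] == src]
        for mask in range(1, 2 ** len(idx)):
            subset = tuple(idx[j] for j in range(len(idx)) if mask >> j & 1)
            new = "".join(dst if i in subset else codon[i] for i in range(3))
            if new in STOPS:
                out.add(
                    (
                        subset,
                        tuple(src for _ in subset),
                        tuple(dst for _ in subset),
                        new,
                    )
                )
    return out


def plan_key(plan) -> tuple:
    """Canonical tuple for a pestop SubstitutionPlan."""
    return (plan.positions, plan.from_bases, plan.to_bases, plan.product)
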