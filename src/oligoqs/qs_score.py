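"""QS-score: similarity of two quaternary structures via shared contacts.

With a chain/residue mapping between assemblies A and B, every inter-chain
contact (representative-atom distance < 12 Å) is *shared* when both of its
residues are mapped and the mapped residue pair is also a contact in the
other assembly; otherwise it is *non-shared*.  The score is

    QS = sum_shared w(min(dA,dB)) * (1 - |dA-dB|/12)
         -----------------------------------------------------------
         sum_shared w(min(dA,dB)) + sum_nsA w(dA) + sum_nsB w(dB)

with the side-chain interaction weight

    w(d) = 1                          for d <= 5 Å
    w(d) = exp(-2 ((d-5)/4.28)^2)     for d  > 5 Å

(half-Gaussian fit to observed side-chain contact distances).  The score is
1 for identical interfaces and tends to 0 for disjoint binding modes or
stoichiometry mismatches (extra contacts of the larger oligomer count as
non-shared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chain_mapping import ChainMapping, ResidueMapping, map_chains
from .contact_map import DEFAULT_CUTOFF, interface_contacts
from .structure_model import Assembly

WEIGHT_PLATEAU = 5.0   # Å, below which w(d) = 1
WEIGHT_SIGMA = 4.28    # Å, half-Gaussian width
MAX_ERROR = 12.0       # Å, maximal distance error in the numerator


@dataclass
class QSResult:
    qs_score: float
    n_shared: int
    n_nonshared_a: int
    n_nonshared_b: int
    mapping: ChainMapping


def contact_weight(d: float) -> float:
    """Probability-like weight of a side-chain interaction at Cβ distance d."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d <= WEIGHT_PLATEAU:
        return 1.0
    return math.exp(-2.0 * ((d - WEIGHT_PLATEAU) / WEIGHT_SIGMA) ** 2)


def qs_score(a: Assembly, b: Assembly, cutoff: float = DEFAULT_CUTOFF,
             mapping: tuple | None = None,
             max_brute: int | None = None) -> QSResult:
    """QS-score between two assemblies.

    ``mapping`` may supply a precomputed ``(ChainMapping, ResidueMapping)``;
    otherwise :func:`map_chains` is run.  Two assemblies that both have no
    inter-chain contacts at all (e.g. monomers) trivially have identical —
    empty — interfaces and score 1.0.
    """
    if mapping is None:
        kwargs = {} if max_brute is None else {"max_brute": max_brute}
        cm, rm = map_chains(a, b, **kwargs)
    else:
        cm, rm = mapping
    fwd = rm.as_dict()

    contacts_a = interface_contacts(a, cutoff)
    contacts_b = interface_contacts(b, cutoff)

    shared = []          # (dA, dB)
    nonshared_a = []     # dA
    matched_b_keys = set()
    for (ra, rb_), d_a in contacts_a.contacts.items():
        ma, mb = fwd.get(ra), fwd.get(rb_)
        if ma is not None and mb is not None:
            key = tuple(sorted((ma, mb)))
            d_b = contacts_b.contacts.get(key)
            if d_b is not None:
                shared.append((d_a, d_b))
                matched_b_keys.add(key)
                continue
        nonshared_a.append(d_a)
    nonshared_b = [d for key, d in contacts_b.contacts.items()
                   if key not in matched_b_keys]

    num = 0.0
    den = 0.0
    for d_a, d_b in shared:
        w = contact_weight(min(d_a, d_b))
        num += w * (1.0 - abs(d_a - d_b) / MAX_ERROR)
        den += w
    den += sum(contact_weight(d) for d in nonshared_a)
    den += sum(contact_weight(d) for d in nonshared_b)

    score = 1.0 if den == 0.0 else num / den
    score = min(max(score, 0.0), 1.0)
    return QSResult(score, len(shared), len(nonshared_a), len(nonshared_b), cm)


def qs_result_json(res: QSResult) -> dict:
    return {"qs_score": res.qs_score,
            "n_shared": res.n_shared,
            "n_nonshared_a": res.n_nonshared_a,
            "n_nonshared_b": res.n_nonshared_b,
            "chain_pairs": list(map(list, res.mapping.pairs)),
            "mapping_rmsd": res.mapping.rmsd,
            "mapping_method": res.mapping.method}
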