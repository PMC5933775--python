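"""Saidman-style synthetic KPD pool generator.

The generator emulates registry pools the way kidney-exchange simulators in
this literature do: donor and patient ABO groups are drawn from population
frequencies, each patient carries a sensitization level (PRA, the probability
that an ABO-compatible donor fails the crossmatch), and a candidate pair is
kept only if it is internally *incompatible* (otherwise the pair would have
transplanted directly and never entered the pool).  A directed arc i -> j is
then emitted when donor i is ABO-compatible with patient j and an independent
Bernoulli crossmatch draw with success probability 1 - PRA_j passes.

Because pairs are kept only when internally incompatible, the retained pool
over-represents highly sensitized patients and O patients; the resulting arc
density is what makes clearing non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pool import BloodType, CompatRelation, KPDPool, NodeKind, PoolNode

__all__ = ["GeneratorParams", "generate_pool", "SAIDMAN_BLOOD_FREQUENCIES"]

#: Classical Saidman-model ABO frequencies for the US population.
SAIDMAN_BLOOD_FREQUENCIES: dict[BloodType, float] = {
    BloodType.O: 0.4814,
    BloodType.A: 0.3373,
    BloodType.B: 0.1428,
    BloodType.AB: 0.0385,
}

# Integer codes used internally for vectorised compatibility tests.
_CODES = (BloodType.O, BloodType.A, BloodType.B, BloodType.AB)
_O, _AB = 0, 3


@dataclass
class GeneratorParams:
    """Tunable distributions of the pool generator.

    sensitization_levels
        ``(pra, probability)`` pairs: each patient draws one PRA level.  The
        default mix is weighted toward highly sensitized patients, matching
        the sparse exchange pools that accumulate in real registries (easy
        pairs clear directly and never register); see docs/methods.md for the
        calibration target.
    altruistic_fraction
        Default number of altruistic donors is ``ceil(fraction * n_pairs)``.
    """

    blood_type_frequencies: dict[BloodType, float] = field(
        default_factory=lambda: dict(SAIDMAN_BLOOD_FREQUENCIES)
    )
    sensitization_levels: tuple[tuple[float, float], ...] = (
        (0.05, 0.08),
        (0.80, 0.22),
        (0.995, 0.70),
    )
    altruistic_fraction: float = 0.05
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.blood_type_frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"blood-type frequencies must sum to 1, got {total}")
        ptotal = sum(p for _, p in self.sensitization_levels)
        if not math.isclose(ptotal, 1.0, abs_tol=1e-6):
            raise ValueError(f"sensitization-level probabilities must sum to 1, got {ptotal}")
        for pra, _ in self.sensitization_levels:
            if not 0.0 <= pra <= 1.0:
                raise ValueError(f"sensitization level {pra} outside [0, 1]")

    @property
    def frequency_vector(self) -> np.ndarray:
        return np.array([self.blood_type_frequencies[bt] for bt in _CODES], dtype=float)


def _compatible(donor_codes: np.ndarray, patient_codes: np.ndarray) -> np.ndarray:
    """Vectorised ABO rule: O donates to anyone, AB receives from anyone,
    identical groups match."""
    return (donor_codes == _O) | (patient_codes == _AB) | (donor_codes == patient_codes)


def generate_pool(
    n_pairs: int,
    n_altruistic: int | None = None,
    params: GeneratorParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> KPDPool:
    """Draw a synthetic KPD pool of ``n_pairs`` incompatible pairs plus
    altruistic donors.

    Every retained pair is internally incompatible: candidate pairs whose own
    donor is ABO-compatible with the patient *and* passes the crossmatch draw
    are resampled.  Cross-pair arcs get independent crossmatch draws against
    the recipient's sensitization.  Fully reproducible given ``seed``.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    params = params or GeneratorParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_altruistic is None:
        n_altruistic = math.ceil(params.altruistic_fraction * n_pairs)

    freqs = params.frequency_vector
    pra_values = np.array([v for v, _ in params.sensitization_levels])
    pra_probs = np.array([p for _, p in params.sensitization_levels])

    donor = rng.choice(4, size=n_pairs, p=freqs)
    patient = rng.choice(4, size=n_pairs, p=freqs)
    pra = pra_values[rng.choice(len(pra_values), size=n_pairs, p=pra_probs)]
    # Reject internally *compatible* pairs: ABO match and crossmatch pass.
    # Each candidate pair gets exactly one crossmatch draw; only rejected
    # slots are redrawn.
    idx = np.arange(n_pairs)
    while idx.size:
        ok = _compatible(donor[idx], patient[idx]) & (rng.random(idx.size) < 1.0 - pra[idx])
        idx = idx[ok]
        if idx.size == 0:
            break
        donor[idx] = rng.choice(4, size=idx.size, p=freqs)
        patient[idx] = rng.choice(4, size=idx.size, p=freqs)
        pra[idx] = pra_values[rng.choice(len(pra_values), size=idx.size, p=pra_probs)]

    alt_donor = rng.choice(4, size=n_altruistic, p=freqs)

    nodes = [
        PoolNode(
            id=i,
            kind=NodeKind.PAIR,
            donor_blood=_CODES[donor[i]],
            patient_blood=_CODES[patient[i]],
            sensitization=float(pra[i]),
        )
        for i in range(n_pairs)
    ]
    nodes += [
        PoolNode(id=n_pairs + a, kind=NodeKind.ALTRUISTIC, donor_blood=_CODES[alt_donor[a]])
        for a in range(n_altruistic)
    ]

    relations: list[CompatRelation] = []
    all_donor_codes = np.concatenate([donor, alt_donor]) if n_altruistic else donor
    for i in range(n_pairs + n_altruistic):
        if n_pairs == 0:
            break
        mask = _compatible(np.full(n_pairs, all_donor_codes[i]), patient)
        mask &= rng.random(n_pairs) < 1.0 - pra
        if i < n_pairs:
            mask[i] = False  # retained pairs are internally incompatible
        for j in np.flatnonzero(mask):
            relations.append(CompatRelation(i, int(j), params.default_weight))

    return KPDPool(nodes, relations)
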