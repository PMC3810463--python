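"""Family structures: simulation of multi-generation pedigrees and expected kinship.

The study design emulated here is a family cohort re-recruited from
three-generation pedigrees at two field centers.  Each simulated family is
founded by a couple; their children marry unrelated spouses (who join the
family as founders) and produce a third generation.  Sibship sizes are
``1 + Poisson(mean_sibs - 1)`` so the expected sibship size equals
``mean_sibs`` while every couple has at least one child.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["PedigreeSample", "simulate_pedigrees", "pedigree_to_frame", "kinship_matrix"]


@dataclass(frozen=True)
class PedigreeSample:
    """One individual in a pedigree.

    Parent IDs are either both present or both missing (``None``); parents
    always belong to the same family.  ``generation`` is 1 for the founding
    couple's generation.
    """

    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female"
    center: str  # "A" | "B"
    generation: int

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError("parent IDs must be both present or both missing")
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.generation < 1:
            raise ValueError("generation must be >= 1")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


def _sibship_size(rng: np.random.Generator, mean_sibs: float) -> int:
    # shifted Poisson: support >= 1, mean exactly mean_sibs
    return 1 + int(rng.poisson(max(mean_sibs - 1.0, 0.0)))


def simulate_pedigrees(
    n_families: int,
    generations: int,
    mean_sibs: float = 2.0,
    seed: int = 0,
) -> list[PedigreeSample]:
    """Simulate ``n_families`` independent pedigrees of up to three generations.

    Families are assigned to centers A/B with equal probability at the family
    level.  Spouses marrying into a family are founders (missing parents)
    recorded under the same family ID.

    Parameters
    ----------
    n_families : int
        Number of independent families (>= 1).
    generations : int
        Pedigree depth, one of {1, 2, 3}.
    mean_sibs : float
        Expected number of children per couple (>= 1).
    seed : int
        Seed for all randomness in this call.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if generations not in (1, 2, 3):
        raise ValueError("generations must be in {1, 2, 3}")
    if mean_sibs < 1:
        raise ValueError("mean_sibs must be >= 1")
    rng = np.random.default_rng(seed)

    samples: list[PedigreeSample] = []
    for f in range(n_families):
        fid = f"F{f + 1:04d}"
        center = "A" if rng.random() < 0.5 else "B"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_I{counter:03d}"

        father = PedigreeSample(fid, new_id(), None, None, "male", center, 1)
        mother = PedigreeSample(fid, new_id(), None, None, "female", center, 1)
        samples += [father, mother]
        if generations == 1:
            continue

        couples = [(father, mother)]
        for gen in range(2, generations + 1):
            next_couples = []
            for dad, mom in couples:
                for _ in range(_sibship_size(rng, mean_sibs)):
                    sex = "male" if rng.random() < 0.5 else "female"
                    child = PedigreeSample(
                        fid, new_id(), dad.individual_id, mom.individual_id, sex, center, gen
                    )
                    samples.append(child)
                    if gen < generations:
                        spouse = PedigreeSample(
                            fid,
                            new_id(),
                            None,
                            None,
                            "female" if sex == "male" else "male",
                            center,
                            gen,
                        )
                        samples.append(spouse)
                        pair = (child, spouse) if sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    return samples


def pedigree_to_frame(pedigree: list[PedigreeSample]) -> pd.DataFrame:
    """Tabulate a pedigree as a DataFrame with PLINK-style columns.

    Missing parents are encoded as "0"; sex as 1=male, 2=female.
    """
    return pd.DataFrame(
        {
            "fid": [s.family_id for s in pedigree],
            "iid": [s.individual_id for s in pedigree],
            "father": [s.father_id or "0" for s in pedigree],
            "mother": [s.mother_id or "0" for s in pedigree],
            "sex": [1 if s.sex == "male" else 2 for s in pedigree],
            "center": [s.center for s in pedigree],
            "generation": [s.generation for s in pedigree],
        }
    )


def kinship_matrix(pedigree: pd.DataFrame) -> np.ndarray:
    """Expected numerator relationship matrix (2x kinship coefficient).

    Computed by the standard tabular recursion, processing individuals in an
    order where parents precede children.  Diagonal is 1 + F (inbreeding);
    parent-offspring and full-sib entries are 0.5 in outbred pedigrees.
    """
    ped = pedigree.reset_index(drop=True)
    iid = list(ped["iid"])
    idx = {v: i for i, v in enumerate(iid)}
    n = len(iid)
    father = [idx.get(f, -1) for f in ped["father"]]
    mother = [idx.get(m, -1) for m in ped["mother"]]

    # topological order: founders first, then by resolved parents
    order: list[int] = []
    placed = np.zeros(n, dtype=bool)
    remaining = set(range(n))
    while remaining:
        ready = [
            i
            for i in remaining
            if (father[i] < 0 or placed[father[i]]) and (mother[i] < 0 or placed[mother[i]])
        ]
        if not ready:
            raise ValueError("pedigree contains a cycle")
        for i in ready:
            placed[i] = True
            order.append(i)
        remaining -= set(ready)

    A = np.zeros((n, n))
    for pos, i in enumerate(order):
        f, m = father[i], mother[i]
        for j in order[:pos]:
            a = 0.0
            if f >= 0:
                a += 0.5 * A[f, j]
            if m >= 0:
                a += 0.5 * A[m, j]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[f, m] if f >= 0 and m >= 0 else 0.0)
    return A
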