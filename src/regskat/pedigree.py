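"""Pedigree parsing and pedigree-based kinship.

The kinship coefficient phi_ij is the probability that a random allele
drawn from individual i is identical by descent with a random allele
from j.  Under an additive polygenic model the expected genetic
covariance between relatives is proportional to 2*phi, which is the
random-effect covariance structure used by the mixed-model tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PedigreeError", "Individual", "Pedigree", "read_pedigree", "kinship",
           "KinshipMatrix", "relatedness_covariance", "write_kinship"]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: Optional[str]  # None = founder on that side
    mother_id: Optional[str]
    sex: int  # 1 male, 2 female, 0 unknown


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise PedigreeError(f"duplicated individual ID {dup!r}")
        known = set(ids)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind.individual_id!r} not in pedigree"
                    )
        self._topological_order()  # raises on cycles

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def _topological_order(self) -> list[Individual]:
        """Founders-first ordering (Kahn's algorithm); errors on cycles."""
        by_id = {ind.individual_id: ind for ind in self.individuals}
        indeg = {i: 0 for i in by_id}
        children: dict[str, list[str]] = {i: [] for i in by_id}
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    indeg[ind.individual_id] += 1
                    children[parent].append(ind.individual_id)
        queue = [i for i in by_id if indeg[i] == 0]
        order = []
        while queue:
            cur = queue.pop()
            order.append(by_id[cur])
            for ch in children[cur]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(self.individuals):
            stuck = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {stuck[:5]}")
        return order

    def topological(self) -> list[Individual]:
        return self._topological_order()

    def add_founders(self, ids: Sequence[str], family_prefix: str = "orphan") -> "Pedigree":
        """Return a pedigree extended with the given IDs as unrelated founders."""
        extra = [
            Individual(f"{family_prefix}_{i}", iid, None, None, 0)
            for i, iid in enumerate(ids)
        ]
        return Pedigree(self.individuals + extra)


def read_pedigree(path) -> Pedigree:
    """Read a PED/FAM-style whitespace-delimited file (first 5 columns used)."""
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(f"{path}:{lineno}: expected >= 5 columns")
            fam, iid, fid, mid, sex = fields[:5]
            try:
                sex_i = int(sex)
            except ValueError:
                sex_i = 0
            individuals.append(
                Individual(
                    fam,
                    iid,
                    None if fid == MISSING_PARENT else fid,
                    None if mid == MISSING_PARENT else mid,
                    sex_i,
                )
            )
    try:
        return Pedigree(individuals)
    except PedigreeError as err:
        raise PedigreeError(f"{path}: {err}") from err


@dataclass
class KinshipMatrix:
    ids: list[str]
    phi: np.ndarray  # symmetric, kinship coefficients

    def subset(self, keep_ids: Sequence[str]) -> "KinshipMatrix":
        """Subset to the given IDs (in the given order), after full computation.

        Subsetting after computing on the whole pedigree preserves
        relatedness transmitted through individuals who are themselves
        excluded from the analysis.
        """
        index = {iid: k for k, iid in enumerate(self.ids)}
        missing = [i for i in keep_ids if i not in index]
        if missing:
            raise PedigreeError(f"IDs not in kinship matrix: {missing[:5]}")
        sel = np.array([index[i] for i in keep_ids])
        return KinshipMatrix(list(keep_ids), self.phi[np.ix_(sel, sel)])


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the standard recursive (tabular) method.

    Processing individuals founders-first, with f/m the parents of i:
      phi(i,i) = 1/2 (1 + phi(f, m))          [> 1/2 under inbreeding]
      phi(i,j) = 1/2 (phi(f, j) + phi(m, j))  for j placed before i
    Founders are mutually unrelated and non-inbred; a missing parent
    contributes zero relatedness.
    """
    order = ped.topological()
    n = len(order)
    phi = np.zeros((n, n))
    pos = {ind.individual_id: k for k, ind in enumerate(order)}
    for k, ind in enumerate(order):
        fa = pos.get(ind.father_id) if ind.father_id else None
        mo = pos.get(ind.mother_id) if ind.mother_id else None
        if fa is None and mo is None:
            phi[k, k] = 0.5
        else:
            parent_phi = phi[fa, mo] if (fa is not None and mo is not None) else 0.0
            phi[k, k] = 0.5 * (1.0 + parent_phi)
        for j in range(k):
            val = 0.0
            if fa is not None:
                val += 0.5 * phi[fa, j]
            if mo is not None:
                val += 0.5 * phi[mo, j]
            phi[k, j] = phi[j, k] = val
    # present in the pedigree's original row order
    want = [pos[i] for i in ped.ids]
    sel = np.array(want)
    return KinshipMatrix(ped.ids, phi[np.ix_(sel, sel)])


def relatedness_covariance(kin: KinshipMatrix, tol: float = 1e-8) -> np.ndarray:
    """Random-effect covariance structure 2*Phi (unit diagonal when non-inbred)."""
    cov = 2.0 * kin.phi
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -tol * max(1.0, float(np.abs(cov).max())):
        raise PedigreeError(f"2*Phi not positive semidefinite (min eigenvalue {eigmin:.3g})")
    return cov


def write_kinship(kin: KinshipMatrix, path) -> None:
    pd.DataFrame(kin.phi, index=kin.ids, columns=kin.ids).to_csv(path, sep="\t")
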