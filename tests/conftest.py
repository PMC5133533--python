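import numpy as np
import pytest

from regskat.pedigree import Individual, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def trio_ped(tmp_path):
    path = tmp_path / "trio.ped"
    path.write_text(
        "FAM1 DAD 0 0 1\n"
        "FAM1 MOM 0 0 2\n"
        "FAM1 KID DAD MOM 1\n"
    )
    return path


@pytest.fixture
def three_generation_pedigree():
    """Grandparents, three children (one married to an outside spouse),
    and two grandchildren; plus an unrelated second family."""
    return Pedigree([
        Individual("F1", "GP1", None, None, 1),
        Individual("F1", "GP2", None, None, 2),
        Individual("F1", "C1", "GP1", "GP2", 1),
        Individual("F1", "C2", "GP1", "GP2", 2),
        Individual("F1", "C3", "GP1", "GP2", 1),
        Individual("F1", "SP1", None, None, 2),
        Individual("F1", "GC1", "C1", "SP1", 1),
        Individual("F1", "GC2", "C1", "SP1", 2),
        Individual("F2", "X1", None, None, 1),
        Individual("F2", "X2", None, None, 2),
        Individual("F2", "Y1", "X1", "X2", 1),
    ])


def gene_drop_kinship(ped, pair_ids, n_rep, rng):
    """Monte-Carlo kinship via gene dropping with unique founder labels.

    Independent of the recursive kinship algorithm: founders get globally
    unique allele labels, transmission is simulated, and phi is estimated
    as the IBD probability of one random allele from each individual.
    """
    order = ped.topological()
    haps = {}
    label = 0
    for ind in order:
        if ind.father_id is None and ind.mother_id is None:
            h = np.empty((n_rep, 2), dtype=np.int32)
            h[:, 0] = label
            h[:, 1] = label + 1
            haps[ind.individual_id] = h
            label += 2
        else:
            cols = []
            for parent in (ind.father_id, ind.mother_id):
                pick = rng.integers(0, 2, size=n_rep)
                cols.append(haps[parent][np.arange(n_rep), pick])
            haps[ind.individual_id] = np.column_stack(cols)
    out = {}
    for a, b in pair_ids:
        ha, hb = haps[a], haps[b]
        ibd = np.zeros(n_rep)
        for i in range(2):
            for j in range(2):
                ibd += ha[:, i] == hb[:, j]
        out[(a, b)] = float(np.mean(ibd) / 4.0)
    return out


@pytest.fixture
def gene_dropper():
    return gene_drop_kinship


@pytest.fixture
def halfsib_pedigree():
    """Two mothers sharing one father: H1 and H2 are half siblings."""
    return Pedigree([
        Individual("F1", "DAD", None, None, 1),
        Individual("F1", "M1", None, None, 2),
        Individual("F1", "M2", None, None, 2),
        Individual("F1", "H1", "DAD", "M1", 1),
        Individual("F1", "H2", "DAD", "M2", 2),
    ])
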