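import numpy as np
import pandas as pd
import pytest

from salmap import FamilyDataset, FamilyLinkageModel, SimulationConfig, simulate_family
from salmap.io import MarkerDef
from salmap.mapping import TwoPointTable
from salmap.twopoint import lod_score


@pytest.fixture(scope="session")
def default_family():
    """The reference simulated family: 48 offspring, 361 markers on 34
    chromosomes, female:male ratio 5.4, seed fixed."""
    return simulate_family(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_family):
    ds, truth = default_family
    model = FamilyLinkageModel(
        ds, annotations=truth.annotations, donor_karyotype=truth.donor_karyotype
    )
    return model.fit()


def make_dataset(rows: dict[str, dict], grandparents: bool = False) -> FamilyDataset:
    """Build a small family dataset from per-marker genotype dictionaries.

    Each row maps marker name -> {"dam": (a, b), "sire": (a, b),
    "off": [(a, b), ...], optionally "gs1".."gd2"}.
    """
    n_off = len(next(iter(rows.values()))["off"])
    ids, gens, roles = [], [], []
    if grandparents:
        ids += ["GS1", "GD1", "GS2", "GD2"]
        gens += ["F0"] * 4
        roles += ["grandsire1", "granddam1", "grandsire2", "granddam2"]
    ids += ["DAM", "SIRE"] + [f"O{i + 1}" for i in range(n_off)]
    gens += ["F1"] * 2 + ["F2"] * n_off
    roles += ["dam", "sire"] + ["offspring"] * n_off
    individuals = pd.DataFrame(
        {"id": ids, "generation": gens, "role": roles, "sex": ["unknown"] * len(ids)}
    )
    markers = [MarkerDef(name=name) for name in rows]
    geno = np.zeros((len(rows), len(ids), 2), dtype=np.int32)
    for mi, (name, row) in enumerate(rows.items()):
        col = 0
        if grandparents:
            for key in ("gs1", "gd1", "gs2", "gd2"):
                geno[mi, col] = row.get(key, (0, 0))
                col += 1
        geno[mi, col] = row["dam"]
        geno[mi, col + 1] = row["sire"]
        for k, call in enumerate(row["off"]):
            geno[mi, col + 2 + k] = call
    return FamilyDataset(individuals=individuals, markers=markers, genotypes=geno)


def make_table(names: list[str], counts: dict[frozenset, tuple[int, int]]) -> TwoPointTable:
    """TwoPointTable from explicit per-pair (N, R) counts; absent pairs
    have no data."""
    k = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    n = np.zeros((k, k), dtype=np.int64)
    r = np.zeros((k, k), dtype=np.int64)
    for pair, (nn, rr) in counts.items():
        a, b = sorted(pair)
        i, j = idx[a], idx[b]
        n[i, j] = n[j, i] = nn
        r[i, j] = r[j, i] = rr
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, r / np.maximum(n, 1), 0.5)
    lod = np.where(n > 0, lod_score(r, np.maximum(n, 1)), 0.0)
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(lod, 0.0)
    return TwoPointTable(names=names, n=n, r=r, theta=theta, lod=lod)


def true_linear_positions(truth) -> dict[str, float]:
    """Signed position of every marker along its chromosome (first arm
    negated so the metacentric order runs telomere-centromere-telomere)."""
    pos: dict[str, float] = {}
    for chrom in truth.genome.chromosomes:
        signs = [-1.0, 1.0] if len(chrom.arms) == 2 else [1.0]
        for sign, arm in zip(signs, chrom.arms):
            for name, p in zip(arm.marker_names, arm.positions_female):
                pos[name] = sign * float(p)
    return pos


def order_matches_truth(
    markers: list[str],
    table: TwoPointTable,
    positions: dict[str, float],
) -> bool:
    """True when the marker order agrees with the true positions up to
    reversal, excusing pairs with zero observed recombinants (such pairs
    are not orderable from the data)."""
    for seq in (markers, list(reversed(markers))):
        ok = True
        for i in range(len(seq)):
            for j in range(i + 1, len(seq)):
                if positions[seq[i]] > positions[seq[j]]:
                    ii, jj = table.index.get(seq[i]), table.index.get(seq[j])
                    if (
                        ii is None
                        or jj is None
                        or table.n[ii, jj] == 0
                        or table.r[ii, jj] > 0
                    ):
                        ok = False
        if ok:
            return True
    return False
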