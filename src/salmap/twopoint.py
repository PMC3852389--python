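"""Two-point linkage analysis for a single outbred family.

Each F1 parent's heterozygous markers define that parent's meioses
(pseudo-testcross logic): every offspring is coded by which parental
haplotype it received.  For a marker pair the recombination fraction is
estimated by recombinant counting over offspring informative at both
markers, with linkage phase chosen to minimise recombinants, and supported
by the LOD score

    LOD = R log10(2 theta) + (N - R) log10(2 (1 - theta)),  theta = R / N,

the log10 likelihood ratio against free recombination (theta = 1/2).
Offspring whose genotype is compatible with both parental alleles (possible
only when the parents share alleles) are excluded pairwise rather than
resolved by EM, so N is always a count of unambiguous meioses.

Map distances come from the classical map functions (Morgan 100*theta,
Haldane, Kosambi); under near-complete crossover interference theta itself
is additive along an arm and the Morgan distance is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, FamilyDataset

CODE_H0 = 0
CODE_H1 = 1
CODE_AMBIGUOUS = -1
CODE_MISSING = -2


@dataclass
class TransmissionVector:
    """Per-offspring haplotype codes for one marker in one parent."""

    parent: str  # dam | sire
    marker: str
    codes: np.ndarray  # int8: 0/1 haplotype, -1 ambiguous, -2 missing
    phase_known: bool = False  # True when grandparents oriented haplotype 0

    @property
    def n_informative(self) -> int:
        return int(np.sum(self.codes >= 0))


# --------------------------------------------------------------------------
# informativeness
# --------------------------------------------------------------------------

def classify_marker(
    dam: tuple[int, int],
    sire: tuple[int, int],
    grandparents=None,
) -> str:
    """Informativeness class of a marker from the parental genotypes.

    Returns one of ``both_fully_informative`` (ab x cd or ab x ac),
    ``dam_only``/``sire_only`` (ab x cc), ``intercross_shared`` (ab x ab)
    or ``uninformative``.  ``grandparents`` is accepted for signature
    completeness; phase resolution happens in :func:`resolve_phase`.
    """
    if dam[0] == MISSING or sire[0] == MISSING:
        return "uninformative"
    dam_het = dam[0] != dam[1]
    sire_het = sire[0] != sire[1]
    if dam_het and sire_het:
        if set(dam) == set(sire):
            return "intercross_shared"
        return "both_fully_informative"
    if dam_het:
        return "dam_only"
    if sire_het:
        return "sire_only"
    return "uninformative"


def resolve_phase(
    parent_gt: tuple[int, int],
    grandsire_gt: tuple[int, int] | None,
    granddam_gt: tuple[int, int] | None,
) -> tuple[tuple[int, int], bool]:
    """Orient a heterozygous parent's alleles as (grandsire-derived,
    granddam-derived) where the grandparental genotypes allow it.

    Returns ``(ordered alleles, phase_known)``; falls back to sorted allele
    order when the origin cannot be resolved.
    """
    a, b = parent_gt
    canonical = (min(a, b), max(a, b))
    if grandsire_gt is None or granddam_gt is None:
        return canonical, False
    if MISSING in grandsire_gt or MISSING in granddam_gt:
        return canonical, False
    a_gs, a_gd = a in grandsire_gt, a in granddam_gt
    b_gs, b_gd = b in grandsire_gt, b in granddam_gt
    if a_gs and b_gd and not (a_gd and b_gs):
        return (a, b), True
    if b_gs and a_gd and not (b_gd and a_gs):
        return (b, a), True
    return canonical, False


def infer_transmissions(
    ds: FamilyDataset, marker: str, parent: str
) -> TransmissionVector:
    """Code each offspring by the parental haplotype received at a marker.

    Requires the parent to be heterozygous.  Offspring compatible with both
    parental alleles are ``AMBIGUOUS``; missing or parent-incompatible
    genotypes are ``MISSING`` (the latter with a warning, mirroring the
    reader's Mendelian masking).
    """
    mi = ds.marker_index(marker)
    p_idx = ds.dam_index if parent == "dam" else ds.sire_index
    o_idx = ds.sire_index if parent == "dam" else ds.dam_index
    parent_gt = tuple(int(x) for x in ds.genotypes[mi, p_idx])
    other_gt = tuple(int(x) for x in ds.genotypes[mi, o_idx])
    if parent_gt[0] == MISSING or parent_gt[0] == parent_gt[1]:
        raise ValueError(f"parent {parent} is not heterozygous at {marker}")
    gp = ds.grandparent_indices(parent)
    if gp is not None:
        gs = tuple(int(x) for x in ds.genotypes[mi, gp[0]])
        gd = tuple(int(x) for x in ds.genotypes[mi, gp[1]])
        (h0, h1), phase_known = resolve_phase(parent_gt, gs, gd)
    else:
        (h0, h1), phase_known = resolve_phase(parent_gt, None, None)

    other_alleles = (
        None if other_gt[0] == MISSING else other_gt
    )
    codes = np.full(ds.n_offspring, CODE_MISSING, dtype=np.int8)
    incompatible = 0
    for k, oi in enumerate(ds.offspring_indices):
        og = tuple(int(x) for x in ds.genotypes[mi, oi])
        if og[0] == MISSING:
            continue
        feasible = []
        for code, allele in ((CODE_H0, h0), (CODE_H1, h1)):
            if other_alleles is None:
                ok = allele in og
            else:
                ok = any(
                    sorted((allele, b)) == sorted(og) for b in other_alleles
                )
            if ok:
                feasible.append(code)
        if not feasible:
            incompatible += 1
        elif len(feasible) == 2:
            codes[k] = CODE_AMBIGUOUS
        else:
            codes[k] = feasible[0]
    if incompatible:
        warnings.warn(
            f"{marker}/{parent}: {incompatible} offspring incompatible with "
            "parent; coded missing",
            stacklevel=2,
        )
    return TransmissionVector(
        parent=parent, marker=marker, codes=codes, phase_known=phase_known
    )


def transmission_matrix(ds: FamilyDataset, parent: str) -> tuple[list[str], np.ndarray]:
    """Transmission codes for every marker heterozygous in ``parent``.

    Returns (marker names, codes matrix of shape (n_markers, n_offspring)).
    """
    p_idx = ds.dam_index if parent == "dam" else ds.sire_index
    names: list[str] = []
    rows: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for marker in ds.marker_names:
            gt = ds.genotypes[ds.marker_index(marker), p_idx]
            if gt[0] == MISSING or gt[0] == gt[1]:
                continue
            names.append(marker)
            rows.append(infer_transmissions(ds, marker, parent).codes)
    codes = (
        np.vstack(rows) if rows else np.zeros((0, ds.n_offspring), dtype=np.int8)
    )
    return names, codes


# --------------------------------------------------------------------------
# two-point estimation
# --------------------------------------------------------------------------

@dataclass
class TwoPointResult:
    parent: str
    marker_a: str
    marker_b: str
    n: int
    r: int
    theta: float
    lod: float
    phase_flipped: bool


def lod_score(r: int | np.ndarray, n: int | np.ndarray):
    """LOD at the ML estimate theta = r/n, with the 0 log 0 := 0 limits."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        t1 = np.where(r > 0, r * np.log10(2 * theta), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log10(2 * (1 - theta)), 0.0)
    out = np.where(n > 0, t1 + t2, 0.0)
    return out if out.ndim else float(out)


def estimate_two_point(
    ta: TransmissionVector, tb: TransmissionVector
) -> TwoPointResult | None:
    """Recombination fraction and LOD for one marker pair in one parent.

    Counts recombinants over offspring unambiguously coded at both markers,
    flipping phase when that more than halves the count.  Returns ``None``
    for pairs with no shared informative meioses.
    """
    if ta.parent != tb.parent:
        raise ValueError("transmission vectors come from different parents")
    valid = (ta.codes >= 0) & (tb.codes >= 0)
    n = int(valid.sum())
    if n == 0:
        return None
    r_raw = int(np.sum(ta.codes[valid] != tb.codes[valid]))
    flipped = r_raw > n - r_raw
    r = n - r_raw if flipped else r_raw
    theta = r / n
    return TwoPointResult(
        parent=ta.parent,
        marker_a=ta.marker,
        marker_b=tb.marker,
        n=n,
        r=r,
        theta=theta,
        lod=float(lod_score(r, n)),
        phase_flipped=flipped,
    )


def two_point_matrices(codes: np.ndarray) -> dict[str, np.ndarray]:
    """All-pairs two-point estimates from a transmission-code matrix.

    Returns square matrices ``n``, ``r`` (phase-minimised), ``theta``,
    ``lod`` and boolean ``flipped``; diagonal entries are zeroed.
    """
    h0 = (codes == CODE_H0).astype(np.int32)
    h1 = (codes == CODE_H1).astype(np.int32)
    valid = h0 + h1
    n = valid @ valid.T
    mismatch = h0 @ h1.T + h1 @ h0.T
    flipped = mismatch > n - mismatch
    r = np.where(flipped, n - mismatch, mismatch)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, r / np.maximum(n, 1), 0.5)
    lod = lod_score(r, np.maximum(n, 0))
    lod = np.where(n > 0, lod, 0.0)
    for mat in (n, r):
        np.fill_diagonal(mat, 0)
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(lod, 0.0)
    return {"n": n, "r": r, "theta": theta, "lod": lod, "flipped": flipped}


# --------------------------------------------------------------------------
# map functions
# --------------------------------------------------------------------------

MAP_FUNCTIONS = ("morgan", "haldane", "kosambi")


def map_function(theta, kind: str = "kosambi", cap_cm: float = 50.0):
    """Convert recombination fraction(s) to map distance in cM.

    morgan: 100*theta (exact under complete interference);
    haldane: -50 ln(1 - 2 theta); kosambi: 25 ln((1+2 theta)/(1-2 theta)).
    theta = 0.5 maps to ``cap_cm`` (the Morgan bound; the other functions
    diverge there).
    """
    if kind not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {kind!r}")
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("theta must lie in [0, 0.5]")
    at_half = arr >= 0.5
    safe = np.where(at_half, 0.25, arr)
    if kind == "morgan":
        out = 100.0 * arr
    elif kind == "haldane":
        out = np.where(at_half, cap_cm, -50.0 * np.log1p(-2.0 * safe))
    else:
        out = np.where(at_half, cap_cm, 25.0 * (np.log1p(2 * safe) - np.log1p(-2 * safe)))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# sex comparison (recomdif)
# --------------------------------------------------------------------------

@dataclass
class RecomDifResult:
    """Female:male recombination comparison over a set of marker pairs.

    ``ratio`` is the mean female recombinant count divided by the mean male
    recombinant count over the pair set; ``g`` is the pooled 2x2 G-test
    (recombinant/non-recombinant x sex) with 1 degree of freedom.
    """

    pairs: pd.DataFrame  # marker_a, marker_b, r_female, n_female, r_male, n_male
    ratio: float
    ratio_range: tuple[float, float]
    n_pairs: int
    g: float
    df: int
    p_value: float


def g_test_2x2(table: np.ndarray) -> tuple[float, float]:
    """Log-likelihood-ratio (G) test of independence on a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        return 0.0, 1.0
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    return g, float(stats.chi2.sf(g, df=1))


def recomdif(pair_table: pd.DataFrame) -> RecomDifResult:
    """Compare female and male recombination over shared linked pairs.

    ``pair_table`` needs columns marker_a, marker_b, r_female, n_female,
    r_male, n_male (one row per marker pair informative in both sexes).
    """
    if len(pair_table) == 0:
        raise ValueError("empty pair set")
    rf = pair_table["r_female"].to_numpy(dtype=float)
    rm = pair_table["r_male"].to_numpy(dtype=float)
    nf = pair_table["n_female"].to_numpy(dtype=float)
    nm = pair_table["n_male"].to_numpy(dtype=float)
    ratio = float(rf.mean() / rm.mean()) if rm.mean() > 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_pair = np.where(rm > 0, rf / np.maximum(rm, 1e-300), np.nan)
    finite = per_pair[np.isfinite(per_pair)]
    rng = (
        (float(np.min(finite)), float(np.max(finite)))
        if len(finite)
        else (float("nan"), float("nan"))
    )
    table = np.array(
        [[rf.sum(), nf.sum() - rf.sum()], [rm.sum(), nm.sum() - rm.sum()]]
    )
    g, p = g_test_2x2(table)
    return RecomDifResult(
        pairs=pair_table.reset_index(drop=True),
        ratio=ratio,
        ratio_range=rng,
        n_pairs=len(pair_table),
        g=g,
        df=1,
        p_value=p,
    )


def build_recomdif_pairs(
    ds: FamilyDataset,
    groups: list[list[str]],
    female: tuple[list[str], np.ndarray],
    male: tuple[list[str], np.ndarray],
    exclude_duplicated: bool = True,
) -> pd.DataFrame:
    """Assemble the recomdif pair set: pairs of markers co-resident in a
    linkage group and informative in both sexes, excluding duplicated loci
    and the sex locus."""
    fnames, fcodes = female
    mnames, mcodes = male
    frow = {n: i for i, n in enumerate(fnames)}
    mrow = {n: i for i, n in enumerate(mnames)}
    classes = {m.name: m for m in ds.markers}
    rows = []
    for group in groups:
        usable = [
            n
            for n in sorted(group)
            if n in frow
            and n in mrow
            and not (exclude_duplicated and n in classes and classes[n].copy_tag)
            and not (n in classes and classes[n].marker_class == "sex")
            and n != "sex"
        ]
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                a, b = usable[i], usable[j]
                res_f = estimate_two_point(
                    TransmissionVector("dam", a, fcodes[frow[a]]),
                    TransmissionVector("dam", b, fcodes[frow[b]]),
                )
                res_m = estimate_two_point(
                    TransmissionVector("sire", a, mcodes[mrow[a]]),
                    TransmissionVector("sire", b, mcodes[mrow[b]]),
                )
                if res_f is None or res_m is None:
                    continue
                rows.append(
                    {
                        "marker_a": a,
                        "marker_b": b,
                        "r_female": res_f.r,
                        "n_female": res_f.n,
                        "r_male": res_m.r,
                        "n_male": res_m.n,
                    }
                )
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "r_female", "n_female", "r_male", "n_male"]
    )


def results_to_frame(results: list[TwoPointResult]) -> pd.DataFrame:
    """Two-point results as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "parent": r.parent,
                "marker_a": r.marker_a,
                "marker_b": r.marker_b,
                "n": r.n,
                "r": r.r,
                "theta": round(r.theta, 6),
                "lod": round(r.lod, 4),
                "phase_flipped": r.phase_flipped,
            }
            for r in results
        ]
    )
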