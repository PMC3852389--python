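"""Readers and writers for family genotype tables, donor-arm annotations,
linkage maps and comparison reports.

The genotype file is a plain TSV holding one outbred three-generation
family: four header rows (individual id, generation, role, sex) followed by
one row per marker whose cells are ``a/b`` allele pairs (fragment sizes or
allozyme codes); ``0/0`` marks a missing call.  No community standard exists
for multiallelic family genotypes, so the dialect is documented here and
kept spreadsheet-friendly.

Marker names follow salmonid convention: a primer pair that amplifies both
members of a duplicated (homeologous) locus pair yields two markers tagged
``/i`` and ``/ii``.  Donor-map annotations attach a rainbow-trout style arm
label (e.g. ``Omy11p``) to a marker, optionally flagged ``c`` (centromere
region) or ``h`` (maps to the homeolog in the donor).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = 0

GENERATIONS = ("F0", "F1", "F2")
ROLES = (
    "grandsire1",
    "granddam1",
    "grandsire2",
    "granddam2",
    "dam",
    "sire",
    "offspring",
)
SEXES = ("F", "M", "unknown")

ARM_SYMBOLS = ("p", "q", "a")


class FamilyFileError(ValueError):
    """Malformed input file; message carries the offending line number."""


class MendelianError(ValueError):
    """Offspring allele incompatible with its parents (strict mode only)."""


def parse_duplicate_name(name: str) -> tuple[str, str | None]:
    """Split a marker name into (base_name, copy_tag).

    The rightmost ``/i`` or ``/ii`` suffix is the copy tag, so
    ``"A/i/ii" -> ("A/i", "ii")``.
    """
    if name.endswith("/ii"):
        return name[:-3], "ii"
    if name.endswith("/i"):
        return name[:-2], "i"
    return name, None


@dataclass(frozen=True)
class DonorAnnotation:
    """Donor-map placement of one marker: linkage group plus arm designator.

    ``arm`` is ``p``/``q`` for metacentric donor chromosomes, ``a`` for
    acrocentric ones.  ``centromere`` marks loci in the donor centromere
    region; such markers are excluded from arm-homology counting.
    ``homeolog`` marks loci that mapped to the donor homeolog (suspected
    paralog amplification), likewise excluded by default.  ``donor_pos`` is
    an optional within-arm position used for marker-order comparison.
    """

    donor_group: str
    arm: str
    centromere: bool = False
    homeolog: bool = False
    donor_pos: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARM_SYMBOLS:
            raise ValueError(f"unknown arm symbol {self.arm!r}")

    @property
    def arm_label(self) -> str:
        return f"{self.donor_group}{self.arm}"


@dataclass(frozen=True)
class MarkerDef:
    name: str
    marker_class: str = "microsatellite"  # microsatellite | allozyme | sex | est_linked
    annotation: DonorAnnotation | None = None

    @property
    def base_name(self) -> str:
        return parse_duplicate_name(self.name)[0]

    @property
    def copy_tag(self) -> str | None:
        return parse_duplicate_name(self.name)[1]


@dataclass(frozen=True)
class DonorChromosome:
    """One chromosome of the donor karyotype: its arm labels and structure."""

    name: str
    structure: str  # metacentric | acrocentric
    arms: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.arms)
        if self.structure == "metacentric" and n != 2:
            raise ValueError(f"{self.name}: metacentric must have 2 arms")
        if self.structure == "acrocentric" and n != 1:
            raise ValueError(f"{self.name}: acrocentric must have 1 arm")


@dataclass
class FamilyDataset:
    """Genotypes of a three-generation outbred family.

    ``genotypes`` has shape (n_markers, n_individuals, 2) with 0 = missing;
    allele pairs are unordered.  Exactly one dam and one sire; grandparents
    are optional but come as a full set of four.
    """

    individuals: pd.DataFrame  # columns: id, generation, role, sex
    markers: list[MarkerDef]
    genotypes: np.ndarray
    mendel_masked: int = 0
    mendel_cells: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ind = self.individuals
        for col in ("id", "generation", "role", "sex"):
            if col not in ind.columns:
                raise ValueError(f"individuals table lacks column {col!r}")
        roles = ind["role"].tolist()
        if roles.count("dam") != 1 or roles.count("sire") != 1:
            raise ValueError("family must have exactly one dam and one sire")
        n_gp = sum(r.startswith("grand") for r in roles)
        if n_gp not in (0, 4):
            raise ValueError("family must have 0 or 4 grandparents")
        if roles.count("offspring") < 1:
            raise ValueError("family must have at least one offspring")
        if self.genotypes.shape != (len(self.markers), len(ind), 2):
            raise ValueError("genotype matrix dimensions do not match")
        keys = [(m.base_name, m.copy_tag) for m in self.markers]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (base_name, copy_tag) marker keys")

    # --- convenience lookups -------------------------------------------------
    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def _role_index(self, role: str) -> int:
        return int(np.flatnonzero(self.individuals["role"] == role)[0])

    @property
    def dam_index(self) -> int:
        return self._role_index("dam")

    @property
    def sire_index(self) -> int:
        return self._role_index("sire")

    def grandparent_indices(self, parent: str) -> tuple[int, int] | None:
        """(sire-side, dam-side) grandparents of the given F1 parent."""
        tag = "1" if parent == "dam" else "2"
        roles = self.individuals["role"]
        gs = np.flatnonzero(roles == f"grandsire{tag}")
        gd = np.flatnonzero(roles == f"granddam{tag}")
        if len(gs) == 0 or len(gd) == 0:
            return None
        return int(gs[0]), int(gd[0])

    @property
    def offspring_indices(self) -> np.ndarray:
        return np.flatnonzero(self.individuals["role"] == "offspring")

    @property
    def n_offspring(self) -> int:
        return int(len(self.offspring_indices))

    @property
    def offspring_sex(self) -> np.ndarray:
        return self.individuals["sex"].to_numpy()[self.offspring_indices]

    def genotype(self, marker: str, individual_index: int) -> tuple[int, int]:
        g = self.genotypes[self.marker_index(marker), individual_index]
        return int(g[0]), int(g[1])

    def with_marker(self, marker: MarkerDef, calls: np.ndarray) -> "FamilyDataset":
        """Return a copy with one extra marker row appended."""
        geno = np.concatenate([self.genotypes, calls[None, :, :]], axis=0)
        return FamilyDataset(
            individuals=self.individuals.copy(),
            markers=[*self.markers, marker],
            genotypes=geno,
            mendel_masked=self.mendel_masked,
            mendel_cells=list(self.mendel_cells),
        )

    def annotate(self, annotations: dict[str, DonorAnnotation]) -> "FamilyDataset":
        markers = [
            replace(m, annotation=annotations.get(m.name, m.annotation))
            for m in self.markers
        ]
        return FamilyDataset(
            individuals=self.individuals.copy(),
            markers=markers,
            genotypes=self.genotypes.copy(),
            mendel_masked=self.mendel_masked,
            mendel_cells=list(self.mendel_cells),
        )


# --------------------------------------------------------------------------
# genotype TSV
# --------------------------------------------------------------------------

_HEADER_KEYS = ("id", "generation", "role", "sex")


def _parse_call(cell: str, lineno: int) -> tuple[int, int]:
    parts = cell.split("/")
    if len(parts) != 2:
        raise FamilyFileError(f"line {lineno}: malformed call {cell!r}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise FamilyFileError(f"line {lineno}: non-integer allele in {cell!r}") from None
    if (a == MISSING) != (b == MISSING):
        raise FamilyFileError(f"line {lineno}: half-missing call {cell!r}")
    if a < 0 or b < 0:
        raise FamilyFileError(f"line {lineno}: negative allele in {cell!r}")
    return (a, b) if a <= b else (b, a)


def _mendel_consistent(off: tuple[int, int], dam: tuple[int, int], sire: tuple[int, int]) -> bool:
    if off[0] == MISSING:
        return True
    if dam[0] == MISSING or sire[0] == MISSING:
        return True  # cannot test
    o = (off[0], off[1])
    for x, y in ((o[0], o[1]), (o[1], o[0])):
        if x in dam and y in sire:
            return True
    return False


def mendelian_check(ds: FamilyDataset, mode: str = "mask") -> FamilyDataset:
    """Mask (or reject) offspring calls carrying an allele absent from both
    parents.  ``mode`` is ``"mask"`` (default: mask call, warn) or
    ``"strict"`` (raise on the first inconsistency)."""
    dam_i, sire_i = ds.dam_index, ds.sire_index
    bad: list[tuple[str, str]] = []
    ids = ds.individuals["id"].tolist()
    for mi, marker in enumerate(ds.markers):
        dam = tuple(ds.genotypes[mi, dam_i])
        sire = tuple(ds.genotypes[mi, sire_i])
        for oi in ds.offspring_indices:
            off = tuple(ds.genotypes[mi, oi])
            if not _mendel_consistent(off, dam, sire):
                if mode == "strict":
                    raise MendelianError(
                        f"marker {marker.name}, individual {ids[oi]}: "
                        f"offspring call {off} incompatible with parents"
                    )
                bad.append((marker.name, ids[oi]))
                ds.genotypes[mi, oi] = (MISSING, MISSING)
    if bad:
        warnings.warn(
            f"masked {len(bad)} Mendelian-inconsistent call(s)", stacklevel=2
        )
    ds.mendel_masked += len(bad)
    ds.mendel_cells.extend(bad)
    return ds


def read_genotypes(path, mendel: str = "mask") -> FamilyDataset:
    """Read the family genotype TSV dialect into a validated dataset.

    Mendelian-inconsistent offspring calls are masked with a warning by
    default (``mendel="mask"``); pass ``mendel="strict"`` to make them a
    hard error, or ``mendel="ignore"`` to skip the check.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 5:
        raise FamilyFileError("file too short: need 4 header rows and >= 1 marker")
    header: dict[str, list[str]] = {}
    for lineno, key in enumerate(_HEADER_KEYS, start=1):
        cells = lines[lineno - 1].split("\t")
        if cells[0] != key:
            raise FamilyFileError(f"line {lineno}: expected header row {key!r}")
        header[key] = cells[1:]
    n_ind = len(header["id"])
    for key in _HEADER_KEYS[1:]:
        if len(header[key]) != n_ind:
            raise FamilyFileError(f"header row {key!r} has wrong length")
    for lineno, gen in enumerate(header["generation"], start=1):
        if gen not in GENERATIONS:
            raise FamilyFileError(f"line 2: unknown generation {gen!r}")
    for role in header["role"]:
        if role not in ROLES:
            raise FamilyFileError(f"line 3: unknown role {role!r}")
    for sex in header["sex"]:
        if sex not in SEXES:
            raise FamilyFileError(f"line 4: unknown sex {sex!r}")

    individuals = pd.DataFrame(
        {
            "id": header["id"],
            "generation": header["generation"],
            "role": header["role"],
            "sex": header["sex"],
        }
    )
    markers: list[MarkerDef] = []
    rows: list[list[tuple[int, int]]] = []
    for lineno0, line in enumerate(lines[4:], start=5):
        cells = line.split("\t")
        if len(cells) != n_ind + 1:
            raise FamilyFileError(
                f"line {lineno0}: expected {n_ind + 1} columns, got {len(cells)}"
            )
        name = cells[0]
        if name in {m.name for m in markers}:
            raise FamilyFileError(f"line {lineno0}: duplicate marker {name!r}")
        markers.append(MarkerDef(name=name))
        rows.append([_parse_call(c, lineno0) for c in cells[1:]])
    geno = np.array(rows, dtype=np.int32)
    ds = FamilyDataset(individuals=individuals, markers=markers, genotypes=geno)
    if mendel != "ignore":
        ds = mendelian_check(ds, mode=mendel)
    return ds


def write_genotypes(ds: FamilyDataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in _HEADER_KEYS:
            fh.write("\t".join([key, *ds.individuals[key].astype(str)]) + "\n")
        for mi, marker in enumerate(ds.markers):
            cells = [
                f"{min(a, b)}/{max(a, b)}" for a, b in ds.genotypes[mi]
            ]
            fh.write("\t".join([marker.name, *cells]) + "\n")


# --------------------------------------------------------------------------
# annotation and donor-karyotype TSV
# --------------------------------------------------------------------------

def read_annotations(path) -> dict[str, DonorAnnotation]:
    """Read a marker -> donor arm annotation table.

    Columns: marker, donor_group, arm, flags (subset of ``c``/``h``,
    optional), donor_pos (optional float).  Unknown arm symbols and
    duplicate marker rows are hard errors.
    """
    out: dict[str, DonorAnnotation] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    start = 0
    if lines and lines[0].split("\t")[0].lower() == "marker":
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) < 3:
            raise FamilyFileError(f"line {lineno}: need marker, donor_group, arm")
        marker, group, arm = cells[0], cells[1], cells[2]
        if marker in out:
            raise FamilyFileError(f"line {lineno}: duplicate marker {marker!r}")
        if arm not in ARM_SYMBOLS:
            raise FamilyFileError(f"line {lineno}: unknown arm symbol {arm!r}")
        flags = cells[3] if len(cells) > 3 else ""
        flagset = set(flags.replace(",", ""))
        if not flagset <= {"c", "h"}:
            raise FamilyFileError(f"line {lineno}: unknown flag in {flags!r}")
        pos: float | None = None
        if len(cells) > 4 and cells[4] != "":
            try:
                pos = float(cells[4])
            except ValueError:
                raise FamilyFileError(
                    f"line {lineno}: bad donor_pos {cells[4]!r}"
                ) from None
        out[marker] = DonorAnnotation(
            donor_group=group,
            arm=arm,
            centromere="c" in flagset,
            homeolog="h" in flagset,
            donor_pos=pos,
        )
    return out


def write_annotations(annotations: dict[str, DonorAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker\tdonor_group\tarm\tflags\tdonor_pos\n")
        for name in sorted(annotations):
            ann = annotations[name]
            flags = ("c" if ann.centromere else "") + ("h" if ann.homeolog else "")
            pos = "" if ann.donor_pos is None else f"{ann.donor_pos:.6f}"
            fh.write(f"{name}\t{ann.donor_group}\t{ann.arm}\t{flags}\t{pos}\n")


def read_donor_karyotype(path) -> dict[str, DonorChromosome]:
    out: dict[str, DonorChromosome] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    start = 1 if lines and lines[0].startswith("donor_chrom") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) != 3:
            raise FamilyFileError(f"line {lineno}: need donor_chrom, structure, arms")
        name, structure, arms = cells
        if name in out:
            raise FamilyFileError(f"line {lineno}: duplicate chromosome {name!r}")
        out[name] = DonorChromosome(
            name=name, structure=structure, arms=tuple(arms.split(","))
        )
    return out


def write_donor_karyotype(karyotype: dict[str, DonorChromosome], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("donor_chrom\tstructure\tarms\n")
        for name in sorted(karyotype):
            chrom = karyotype[name]
            fh.write(f"{name}\t{chrom.structure}\t{','.join(chrom.arms)}\n")


# --------------------------------------------------------------------------
# map and report output
# --------------------------------------------------------------------------

def _annotation_string(marker: MarkerDef) -> str:
    ann = marker.annotation
    if ann is None:
        return ""
    flags = ("c" if ann.centromere else "") + ("h" if ann.homeolog else "")
    return ann.arm_label + (f"({flags})" if flags else "")


def write_map(gmap, path) -> None:
    """Write a GenomeMap as a stable-ordered TSV.

    Columns: group, rank, marker, cumulative_cM, adjacent_cM, annotation,
    status (framework or accessory).  Cumulative positions carry two
    decimals; reruns are byte-identical.
    """
    marker_defs = {m.name: m for m in getattr(gmap, "marker_defs", [])}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\trank\tmarker\tcumulative_cM\tadjacent_cM\tannotation\tstatus\n")
        for group in gmap.groups:
            cum = 0.0
            for rank, name in enumerate(group.markers):
                adj = group.distances[rank - 1] if rank > 0 else 0.0
                cum += adj
                ann = _annotation_string(marker_defs[name]) if name in marker_defs else ""
                fh.write(
                    f"{group.id}\t{rank + 1}\t{name}\t{cum:.2f}\t{adj:.2f}\t{ann}\tframework\n"
                )
            for name, anchor in sorted(group.accessory):
                ann = _annotation_string(marker_defs[name]) if name in marker_defs else ""
                fh.write(
                    f"{group.id}\t0\t{name}\t{anchor:.2f}\t0.00\t{ann}\taccessory\n"
                )


def read_map(path):
    """Read a map TSV written by :func:`write_map` back into a GenomeMap."""
    from .mapping import GenomeMap, LinkageGroup  # lazy: avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype={"annotation": str}, keep_default_na=False)
    groups: list[LinkageGroup] = []
    for gid, sub in df.groupby("group", sort=False):
        frame = sub[sub["status"] == "framework"]
        markers = frame["marker"].tolist()
        distances = frame["adjacent_cM"].to_numpy(dtype=float)[1:].tolist()
        accessory = [
            (row["marker"], float(row["cumulative_cM"]))
            for _, row in sub[sub["status"] == "accessory"].iterrows()
        ]
        groups.append(
            LinkageGroup(
                id=str(gid),
                markers=markers,
                distances=distances,
                map_function="unknown",
                source="file",
                accessory=accessory,
            )
        )
    return GenomeMap(groups=groups, unassigned=[], map_function="unknown", source="file")


def write_mapchart(gmap, path) -> None:
    """MapChart-style text export: one block per group, ``locus position``."""
    with open(path, "w", encoding="utf-8") as fh:
        for group in gmap.groups:
            fh.write(f"group {group.id}\n")
            cum = 0.0
            entries = []
            for rank, name in enumerate(group.markers):
                if rank > 0:
                    cum += group.distances[rank - 1]
                entries.append((cum, name))
            for name, anchor in group.accessory:
                entries.append((anchor, name))
            for pos, name in sorted(entries, key=lambda t: (t[0], t[1])):
                fh.write(f"{name} {pos:.2f}\n")
            fh.write("\n")


def _json_round(obj):
    if isinstance(obj, dict):
        return {k: _json_round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_round(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Write a comparison/run report as deterministic (sorted, rounded) JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_json_round(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
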