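"""Synthetic outbred three-generation families with a known genome.

The generator emulates the study design used for first-generation salmonid
microsatellite maps: a single F1 dam x F1 sire cross with four genotyped F0
grandparents and ~48 F2 offspring, ~360 multiallelic markers spread over a
karyotype of metacentric (two-armed) and acrocentric (one-armed)
chromosomes, strong heterochiasmy (female recombination several-fold male),
duplicated locus pairs on homeologous arms, and missing data.

Meiosis follows the near-complete-interference model of salmonids: per
chromosome arm, at most one crossover occurs (probability ``p_arm`` for the
parent's sex), placed along the arm in proportion to recombination-fraction
share; the two arms of a metacentric chromosome segregate through a shared
centromere.  Under this model the recombination fraction between two
markers equals the difference of their cumulative positions, so map
distances are additive in theta, which the recovery tests exploit.

Marker positions are stored as cumulative female recombination fractions
from the centromere; male positions are the female positions divided by the
configured female:male ratio, as is the per-arm crossover probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io import DonorAnnotation, DonorChromosome, FamilyDataset, MarkerDef

MISSING = 0

CLASSES = (
    "both_fully_informative",
    "dam_only",
    "sire_only",
    "intercross_shared",
    "uninformative",
)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated family.

    Defaults mirror the reference design: 48 offspring, 34 chromosomes
    (16 metacentric + 18 acrocentric, 50 arms), 361 marker loci including
    16 duplicated pairs grouped into 9 homeologous arm pairings, a
    female:male recombination ratio of 5.4, 5% missing calls, and one
    planted 4-marker inverted block relative to the donor map.
    """

    n_metacentric: int = 16
    n_acrocentric: int = 18
    markers_total: int = 361
    n_offspring: int = 48
    fm_ratio: float = 5.4
    missing_rate: float = 0.05
    error_rate: float = 0.0
    seed: int = 0
    # fractions of markers per informativeness class, in CLASSES order
    class_fractions: tuple[float, ...] = (0.55, 0.15, 0.15, 0.08, 0.07)
    # female per-arm crossover probability range (theta span of one arm)
    arm_span_female: tuple[float, float] = (0.26, 0.38)
    allele_pool_range: tuple[int, int] = (4, 8)
    n_allozymes: int = 3
    # supporting duplicated-locus counts per homeologous arm pairing
    duplicate_counts: tuple[int, ...] = (3, 3, 2, 2, 2, 1, 1, 1, 1)
    duplicate_pool_overlap: float = 0.0
    annotated_fraction: float = 0.8
    centromere_flag_prob: float = 0.15
    plant_inversion: bool = True
    inversion_size: int = 4
    require_orderable: bool = True

    def validate(self) -> None:
        if self.n_metacentric < 0 or self.n_acrocentric < 0:
            raise ValueError("chromosome counts must be non-negative")
        if self.n_metacentric + self.n_acrocentric < 1:
            raise ValueError("need at least one chromosome")
        if self.markers_total < 2:
            raise ValueError("need at least two markers")
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")
        if self.fm_ratio <= 0:
            raise ValueError("female:male ratio must be positive")
        if self.fm_ratio < 1:
            raise ValueError("female:male ratio must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if sum(self.duplicate_counts) * 2 + 1 > self.markers_total:
            raise ValueError("too many duplicated loci for markers_total")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )


# --------------------------------------------------------------------------
# genome truth
# --------------------------------------------------------------------------

@dataclass
class ArmSpec:
    donor_arm_label: str
    marker_names: list[str]
    positions_female: np.ndarray  # cumulative theta from centromere, increasing
    crossover_prob_female: float
    crossover_prob_male: float

    def positions(self, sex: str) -> np.ndarray:
        if sex == "F":
            return self.positions_female
        scale = self.crossover_prob_male / self.crossover_prob_female
        return self.positions_female * scale

    def crossover_prob(self, sex: str) -> float:
        return self.crossover_prob_female if sex == "F" else self.crossover_prob_male

    def validate(self) -> None:
        pos = self.positions_female
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{self.donor_arm_label}: positions not increasing")
        for sex in ("F", "M"):
            if len(pos) and self.positions(sex)[-1] > self.crossover_prob(sex) + 1e-12:
                raise ValueError(
                    f"{self.donor_arm_label}: terminal position exceeds "
                    f"crossover probability for sex {sex}"
                )


@dataclass
class ChromosomeSpec:
    id: str
    structure: str  # metacentric | acrocentric
    arms: list[ArmSpec]

    def validate(self) -> None:
        if self.structure == "metacentric" and len(self.arms) != 2:
            raise ValueError(f"{self.id}: metacentric needs 2 arms")
        if self.structure == "acrocentric" and len(self.arms) != 1:
            raise ValueError(f"{self.id}: acrocentric needs 1 arm")
        for arm in self.arms:
            arm.validate()

    def linear_marker_order(self) -> list[str]:
        """Marker order along the chromosome: first arm telomere-to-
        centromere, then (for metacentrics) second arm outward."""
        if len(self.arms) == 1:
            return list(self.arms[0].marker_names)
        return list(reversed(self.arms[0].marker_names)) + list(self.arms[1].marker_names)


@dataclass
class GenomeSpec:
    chromosomes: list[ChromosomeSpec]
    markers_total: int
    seed: int

    def validate(self) -> None:
        names: list[str] = []
        for chrom in self.chromosomes:
            chrom.validate()
            for arm in chrom.arms:
                names.extend(arm.marker_names)
        if len(set(names)) != len(names):
            raise ValueError("marker names are not unique")

    @property
    def arms(self) -> list[ArmSpec]:
        return [arm for chrom in self.chromosomes for arm in chrom.arms]


@dataclass
class DuplicationSpec:
    base_name: str
    host_arms: tuple[str, str]  # donor_arm_labels, homeologous pair
    pool_overlap: float = 0.0

    @property
    def copy_names(self) -> tuple[str, str]:
        return f"{self.base_name}/i", f"{self.base_name}/ii"


@dataclass
class TruthSet:
    """The simulator's hidden genome: the oracle for recovery tests."""

    genome: GenomeSpec
    duplications: list[DuplicationSpec]
    fm_ratio: float
    classes: dict[str, str]
    pools: dict[str, list[int]]
    marker_class: dict[str, str]
    sex_marker: str
    donor_karyotype: dict[str, DonorChromosome]
    annotations: dict[str, DonorAnnotation]
    inverted_block: tuple[str, list[str]] | None  # (arm label, markers in true order)

    # --- derived lookups -----------------------------------------------------
    @property
    def all_marker_names(self) -> list[str]:
        return [
            name
            for chrom in self.genome.chromosomes
            for arm in chrom.arms
            for name in arm.marker_names
        ]

    @property
    def table_marker_names(self) -> list[str]:
        """Markers emitted in the genotype table (the sex locus travels as
        the offspring sex column instead)."""
        return [n for n in self.all_marker_names if n != self.sex_marker]

    def marker_chromosome(self) -> dict[str, str]:
        out = {}
        for chrom in self.genome.chromosomes:
            for arm in chrom.arms:
                for name in arm.marker_names:
                    out[name] = chrom.id
        return out

    def marker_arm(self) -> dict[str, str]:
        out = {}
        for chrom in self.genome.chromosomes:
            for arm in chrom.arms:
                for name in arm.marker_names:
                    out[name] = arm.donor_arm_label
        return out

    def structures(self) -> dict[str, str]:
        return {c.id: c.structure for c in self.genome.chromosomes}

    def homeolog_chromosome_pairs(self) -> dict[frozenset, int]:
        """Unordered chromosome-pair -> number of supporting duplicated loci."""
        arm_chrom = {
            arm.donor_arm_label: chrom.id
            for chrom in self.genome.chromosomes
            for arm in chrom.arms
        }
        out: dict[frozenset, int] = {}
        for dup in self.duplications:
            pair = frozenset(arm_chrom[a] for a in dup.host_arms)
            out[pair] = out.get(pair, 0) + 1
        return out

    def adjacent_theta(self, sex: str) -> dict[tuple[str, str], float]:
        """True theta between markers adjacent on the same arm."""
        out = {}
        for arm in self.genome.arms:
            pos = arm.positions(sex)
            for i in range(len(arm.marker_names) - 1):
                pair = (arm.marker_names[i], arm.marker_names[i + 1])
                out[pair] = float(pos[i + 1] - pos[i])
        return out

    def pair_theta(self, a: str, b: str, sex: str) -> float:
        """True recombination fraction between any two markers."""
        chrom_of = self.marker_chromosome()
        if chrom_of[a] != chrom_of[b]:
            return 0.5
        chrom = next(c for c in self.genome.chromosomes if c.id == chrom_of[a])

        def locate(name):
            for ai, arm in enumerate(chrom.arms):
                if name in arm.marker_names:
                    i = arm.marker_names.index(name)
                    return ai, float(arm.positions("F")[i]) * (
                        arm.crossover_prob(sex) / arm.crossover_prob("F")
                    )
            raise KeyError(name)

        ai, pa = locate(a)
        bi, pb = locate(b)
        if ai == bi:
            return abs(pa - pb)
        # opposite arms: recombinant iff exactly one centromere-to-marker
        # segment recombines (crossovers on the two arms are independent)
        return pa * (1 - pb) + pb * (1 - pa)

    # --- serialization -------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "fm_ratio": self.fm_ratio,
            "seed": self.genome.seed,
            "markers_total": self.genome.markers_total,
            "sex_marker": self.sex_marker,
            "chromosomes": [
                {
                    "id": c.id,
                    "structure": c.structure,
                    "arms": [
                        {
                            "label": a.donor_arm_label,
                            "markers": a.marker_names,
                            "positions_female": [round(float(x), 12) for x in a.positions_female],
                            "p_female": a.crossover_prob_female,
                            "p_male": a.crossover_prob_male,
                        }
                        for a in c.arms
                    ],
                }
                for c in self.genome.chromosomes
            ],
            "duplications": [
                {
                    "base_name": d.base_name,
                    "host_arms": list(d.host_arms),
                    "pool_overlap": d.pool_overlap,
                }
                for d in self.duplications
            ],
            "classes": self.classes,
            "pools": self.pools,
            "marker_class": self.marker_class,
            "donor_karyotype": {
                k: {"structure": v.structure, "arms": list(v.arms)}
                for k, v in self.donor_karyotype.items()
            },
            "annotations": {
                k: {
                    "donor_group": v.donor_group,
                    "arm": v.arm,
                    "centromere": v.centromere,
                    "homeolog": v.homeolog,
                    "donor_pos": v.donor_pos,
                }
                for k, v in self.annotations.items()
            },
            "inverted_block": (
                None
                if self.inverted_block is None
                else {"arm": self.inverted_block[0], "markers": self.inverted_block[1]}
            ),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        raw = json.loads(text)
        chroms = [
            ChromosomeSpec(
                id=c["id"],
                structure=c["structure"],
                arms=[
                    ArmSpec(
                        donor_arm_label=a["label"],
                        marker_names=list(a["markers"]),
                        positions_female=np.array(a["positions_female"], dtype=float),
                        crossover_prob_female=a["p_female"],
                        crossover_prob_male=a["p_male"],
                    )
                    for a in c["arms"]
                ],
            )
            for c in raw["chromosomes"]
        ]
        genome = GenomeSpec(
            chromosomes=chroms, markers_total=raw["markers_total"], seed=raw["seed"]
        )
        return cls(
            genome=genome,
            duplications=[
                DuplicationSpec(
                    base_name=d["base_name"],
                    host_arms=tuple(d["host_arms"]),
                    pool_overlap=d["pool_overlap"],
                )
                for d in raw["duplications"]
            ],
            fm_ratio=raw["fm_ratio"],
            classes=dict(raw["classes"]),
            pools={k: list(v) for k, v in raw["pools"].items()},
            marker_class=dict(raw["marker_class"]),
            sex_marker=raw["sex_marker"],
            donor_karyotype={
                k: DonorChromosome(name=k, structure=v["structure"], arms=tuple(v["arms"]))
                for k, v in raw["donor_karyotype"].items()
            },
            annotations={
                k: DonorAnnotation(
                    donor_group=v["donor_group"],
                    arm=v["arm"],
                    centromere=v["centromere"],
                    homeolog=v["homeolog"],
                    donor_pos=v["donor_pos"],
                )
                for k, v in raw["annotations"].items()
            },
            inverted_block=(
                None
                if raw["inverted_block"] is None
                else (raw["inverted_block"]["arm"], list(raw["inverted_block"]["markers"]))
            ),
        )

    @classmethod
    def load(cls, path) -> "TruthSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# --------------------------------------------------------------------------
# truth construction
# --------------------------------------------------------------------------

def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _arm_positions(k: int, rng: np.random.Generator) -> np.ndarray:
    """Relative marker positions in (0, 1): roughly even with jitter."""
    if k == 1:
        return np.array([0.5])
    rel = np.linspace(0.08, 0.95, k)
    spacing = (0.95 - 0.08) / (k - 1)
    rel = rel + rng.uniform(-0.35, 0.35, size=k) * spacing
    rel = np.clip(np.sort(rel), 0.02, 0.97)
    for i in range(1, k):  # enforce a minimum gap
        if rel[i] - rel[i - 1] < 0.01:
            rel[i] = rel[i - 1] + 0.01
    return np.minimum(rel, 0.97)


def _build_donor_karyotype(chromosomes: list[ChromosomeSpec]) -> dict[str, DonorChromosome]:
    """Donor karyotype with a fixed mix of conserved chromosomes and
    Robertsonian rearrangements relative to the simulated species.

    Conserved: the first 10 metacentrics and first 2 acrocentrics.  The
    remaining target acrocentric arms are fused pairwise into donor
    metacentrics (fissions in the target lineage); the remaining target
    metacentrics' arms are donor acrocentrics (fusions in the target).
    Arm labels on the simulated genome are assigned from this karyotype.
    """
    meta = [c for c in chromosomes if c.structure == "metacentric"]
    acro = [c for c in chromosomes if c.structure == "acrocentric"]
    donor: dict[str, DonorChromosome] = {}
    counter = 0

    def next_name() -> str:
        nonlocal counter
        counter += 1
        return f"Omy{counter:02d}"

    n_cons_meta = min(10, len(meta))
    for chrom in meta[:n_cons_meta]:
        name = next_name()
        chrom.arms[0].donor_arm_label = f"{name}p"
        chrom.arms[1].donor_arm_label = f"{name}q"
        donor[name] = DonorChromosome(name, "metacentric", (f"{name}p", f"{name}q"))
    n_cons_acro = min(2, len(acro))
    for chrom in acro[:n_cons_acro]:
        name = next_name()
        chrom.arms[0].donor_arm_label = f"{name}a"
        donor[name] = DonorChromosome(name, "acrocentric", (f"{name}a",))
    rest_acro = acro[n_cons_acro:]
    for i in range(0, len(rest_acro) - 1, 2):
        name = next_name()
        rest_acro[i].arms[0].donor_arm_label = f"{name}p"
        rest_acro[i + 1].arms[0].donor_arm_label = f"{name}q"
        donor[name] = DonorChromosome(name, "metacentric", (f"{name}p", f"{name}q"))
    if len(rest_acro) % 2 == 1:
        name = next_name()
        rest_acro[-1].arms[0].donor_arm_label = f"{name}a"
        donor[name] = DonorChromosome(name, "acrocentric", (f"{name}a",))
    for chrom in meta[n_cons_meta:]:
        for arm in chrom.arms:
            name = next_name()
            arm.donor_arm_label = f"{name}a"
            donor[name] = DonorChromosome(name, "acrocentric", (f"{name}a",))
    return donor


def build_truth_genome(config: SimulationConfig) -> TruthSet:
    """Construct the hidden genome (chromosomes, marker positions, sex
    locus, duplications, donor karyotype, annotations) from a config."""
    config.validate()
    rng = _rngs(config.seed, 4)[0]

    n_arms = 2 * config.n_metacentric + config.n_acrocentric
    chromosomes: list[ChromosomeSpec] = []
    for i in range(config.n_metacentric + config.n_acrocentric):
        structure = "metacentric" if i < config.n_metacentric else "acrocentric"
        n_chrom_arms = 2 if structure == "metacentric" else 1
        arms = [
            ArmSpec(
                donor_arm_label="",  # assigned by the donor karyotype below
                marker_names=[],
                positions_female=np.array([]),
                crossover_prob_female=float(
                    rng.uniform(*config.arm_span_female)
                ),
                crossover_prob_male=0.0,
            )
            for _ in range(n_chrom_arms)
        ]
        for arm in arms:
            arm.crossover_prob_male = min(
                0.5, arm.crossover_prob_female / config.fm_ratio
            )
        chromosomes.append(
            ChromosomeSpec(id=f"chr{i + 1:02d}", structure=structure, arms=arms)
        )
    donor_karyotype = _build_donor_karyotype(chromosomes)
    arms = [arm for chrom in chromosomes for arm in chrom.arms]

    # allocate marker counts per arm (near-even coverage, as in a curated
    # mapping panel), then plant duplicated pairs on homeologous arm pairs
    base, rem = divmod(config.markers_total, n_arms)
    counts = np.full(n_arms, base, dtype=int)
    extra = rng.choice(n_arms, size=rem, replace=False)
    counts[extra] += 1
    if config.require_orderable and base < 2:
        raise ValueError("fewer than 2 markers per arm; ordering tests impossible")

    n_pairings = len(config.duplicate_counts)
    arm_chrom = {id(arm): chrom.id for chrom in chromosomes for arm in chrom.arms}
    order = list(rng.permutation(n_arms))
    host_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    idx = 0
    while len(host_pairs) < n_pairings:
        cand = [a for a in order if a not in used]
        a, rest = cand[0], cand[1:]
        partner = next(
            b for b in rest if arm_chrom[id(arms[b])] != arm_chrom[id(arms[a])]
        )
        host_pairs.append((a, partner))
        used.update((a, partner))
        idx += 1

    duplications: list[DuplicationSpec] = []
    dup_slots: dict[int, list[str]] = {i: [] for i in range(n_arms)}
    dup_no = 0
    for (ai, bi), count in zip(host_pairs, config.duplicate_counts):
        for _ in range(count):
            dup_no += 1
            base_name = f"Ogo{dup_no:02d}"
            duplications.append(
                DuplicationSpec(
                    base_name=base_name,
                    host_arms=(arms[ai].donor_arm_label, arms[bi].donor_arm_label),
                    pool_overlap=config.duplicate_pool_overlap,
                )
            )
            dup_slots[ai].append(f"{base_name}/i")
            dup_slots[bi].append(f"{base_name}/ii")

    # name and place markers arm by arm
    reg_no = 0
    for i, arm in enumerate(arms):
        k = int(counts[i])
        if len(dup_slots[i]) > k - 1:
            k = len(dup_slots[i]) + 1  # keep at least one regular marker
        names: list[str] = list(dup_slots[i])
        while len(names) < k:
            reg_no += 1
            names.append(f"Ots{reg_no:03d}")
        perm = rng.permutation(len(names))
        names = [names[j] for j in perm]
        rel = _arm_positions(k, rng)
        arm.marker_names = names
        arm.positions_female = rel * arm.crossover_prob_female

    # sex locus: one extra marker mid-arm on the first acrocentric chromosome
    sex_marker = "sex"
    sex_chrom = next(c for c in chromosomes if c.structure == "acrocentric")
    sarm = sex_chrom.arms[0]
    sex_pos = 0.5 * sarm.crossover_prob_female
    insert = int(np.searchsorted(sarm.positions_female, sex_pos))
    sarm.marker_names.insert(insert, sex_marker)
    sarm.positions_female = np.insert(sarm.positions_female, insert, sex_pos)
    # nudge any coincident neighbours apart
    for j in range(1, len(sarm.positions_female)):
        if sarm.positions_female[j] <= sarm.positions_female[j - 1]:
            sarm.positions_female[j] = sarm.positions_female[j - 1] + 1e-4

    genome = GenomeSpec(
        chromosomes=chromosomes,
        markers_total=config.markers_total,
        seed=config.seed,
    )
    genome.validate()

    # informativeness classes and allele pools
    dup_names = {n for slots in dup_slots.values() for n in slots}
    classes: dict[str, str] = {sex_marker: "sire_only"}
    pools: dict[str, list[int]] = {sex_marker: [1, 2]}
    marker_class: dict[str, str] = {sex_marker: "sex"}
    all_names = [
        n
        for chrom in chromosomes
        for arm in chrom.arms
        for n in arm.marker_names
        if n != sex_marker
    ]
    regular = [n for n in all_names if n not in dup_names]
    allozymes = set(
        rng.choice(regular, size=min(config.n_allozymes, len(regular)), replace=False)
    )
    probs = np.asarray(config.class_fractions)
    for name in all_names:
        if name in dup_names:
            classes[name] = "both_fully_informative"  # mapped duplicated loci
        else:
            classes[name] = CLASSES[int(rng.choice(len(CLASSES), p=probs))]
        if name in allozymes:
            marker_class[name] = "allozyme"
            pools[name] = list(range(1, int(rng.integers(2, 4)) + 1))
        else:
            marker_class[name] = "microsatellite"
            pool = int(rng.integers(config.allele_pool_range[0], config.allele_pool_range[1] + 1))
            start = 100 + 2 * int(rng.integers(0, 40))
            pools[name] = [start + 2 * j for j in range(pool)]
    # duplicated copies: configurable allele-pool overlap (cross-amplification)
    for dup in duplications:
        ni, nii = dup.copy_names
        share = int(round(dup.pool_overlap * len(pools[ni])))
        disjoint = [a + 100 for a in pools[ni]]
        pools[nii] = pools[ni][:share] + disjoint[share:]

    # donor annotations: subset of markers, centromere flags, donor order
    annotations: dict[str, DonorAnnotation] = {}
    arm_of: dict[str, ArmSpec] = {}
    for chrom in chromosomes:
        for arm in chrom.arms:
            for name in arm.marker_names:
                arm_of[name] = arm
    for chrom in chromosomes:
        for arm in chrom.arms:
            label = arm.donor_arm_label
            group, symbol = label[:-1], label[-1]
            flag_first = rng.random() < config.centromere_flag_prob
            for j, name in enumerate(arm.marker_names):
                if name == sex_marker:
                    continue  # species-specific locus, absent from donor map
                if rng.random() > config.annotated_fraction:
                    continue
                rel = float(arm.positions_female[j] / arm.crossover_prob_female)
                annotations[name] = DonorAnnotation(
                    donor_group=group,
                    arm=symbol,
                    centromere=bool(flag_first and j == 0),
                    donor_pos=round(rel, 6),
                )

    inverted_block = _plant_inversion(config, chromosomes, annotations, classes)

    return TruthSet(
        genome=genome,
        duplications=duplications,
        fm_ratio=config.fm_ratio,
        classes=classes,
        pools=pools,
        marker_class=marker_class,
        sex_marker=sex_marker,
        donor_karyotype=donor_karyotype,
        annotations=annotations,
        inverted_block=inverted_block,
    )


def _plant_inversion(
    config: SimulationConfig,
    chromosomes: list[ChromosomeSpec],
    annotations: dict[str, DonorAnnotation],
    classes: dict[str, str],
) -> tuple[str, list[str]] | None:
    """Reverse the donor positions of one wide run of annotated markers on
    one arm, emulating an inversion between the two lineages.

    The run is a set of consecutive annotated markers that are informative
    in the dam, so the block is observable on the female map — the map on
    which such rearrangements are resolved in practice — and is interior:
    at least one equally informative annotated marker flanks it on each
    side.  The
    flanking collinear context both orients the comparison and exposes the
    reversal — a reversal of a whole arm's annotated markers would be
    invisible on strand-free maps.
    """
    if not config.plant_inversion:
        return None
    size = config.inversion_size
    eligible = {"both_fully_informative", "dam_only"}
    best: tuple[float, str, list[str]] | None = None
    for chrom in chromosomes:
        for arm in chrom.arms:
            ann_idx = [
                j
                for j, n in enumerate(arm.marker_names)
                if n in annotations and not annotations[n].centromere
            ]
            if len(ann_idx) < size + 2:  # keep collinear context around the run
                continue
            for s in range(1, len(ann_idx) - size):
                block = ann_idx[s - 1 : s + size + 1]  # window plus flanks
                if any(
                    classes.get(arm.marker_names[j]) not in eligible for j in block
                ):
                    continue
                window = ann_idx[s : s + size]
                span = float(
                    arm.positions_female[window[-1]] - arm.positions_female[window[0]]
                )
                key = (span, arm.donor_arm_label)
                if best is None or key > (best[0], best[1]):
                    best = (span, arm.donor_arm_label, [arm.marker_names[j] for j in window])
    if best is None:
        return None
    _, label, names = best
    pos = [annotations[n].donor_pos for n in names]
    for n, p in zip(names, reversed(pos)):
        old = annotations[n]
        annotations[n] = DonorAnnotation(
            donor_group=old.donor_group,
            arm=old.arm,
            centromere=old.centromere,
            homeolog=old.homeolog,
            donor_pos=p,
        )
    return label, names


# --------------------------------------------------------------------------
# founders
# --------------------------------------------------------------------------

@dataclass
class Founders:
    """F0 genotypes and phased F1 parents.

    ``dam_phase``/``sire_phase`` have shape (2, n_markers): haplotype 0 is
    the grandsire-derived haplotype, haplotype 1 the granddam-derived one.
    F0 genotypes are stored in the order grandsire1, granddam1 (dam side),
    grandsire2, granddam2 (sire side).
    """

    marker_names: list[str]
    f0_genotypes: np.ndarray  # (4, n_markers, 2)
    dam_phase: np.ndarray
    sire_phase: np.ndarray

    def phase(self, parent: str) -> np.ndarray:
        return self.dam_phase if parent == "dam" else self.sire_phase

    def genotype(self, parent: str) -> np.ndarray:
        ph = self.phase(parent)
        return np.sort(ph, axis=0).T  # (n_markers, 2)


def simulate_founders(truth: TruthSet, rng: np.random.Generator) -> Founders:
    """Draw F0 genotypes and phased F1 parents per marker class.

    Classes follow the outbred-cross informativeness taxonomy: fully
    informative (ab x cd, or ab x ac on 3-allele pools), one-parent
    informative (ab x cc), shared-allele intercross (ab x ab), and
    monomorphic/uninformative.  The sex locus is dam-homozygous and
    sire-heterozygous; allele 2 on haplotype 0 of the sire marks males.
    """
    names = truth.all_marker_names
    m = len(names)
    dam_phase = np.zeros((2, m), dtype=np.int32)
    sire_phase = np.zeros((2, m), dtype=np.int32)
    for i, name in enumerate(names):
        pool = truth.pools[name]
        cls = truth.classes[name]
        if name == truth.sex_marker:
            dam_phase[:, i] = (1, 1)
            sire_phase[:, i] = (2, 1)  # haplotype 0 carries the male allele
            continue
        if len(pool) == 1:
            cls = "uninformative"
        if cls == "both_fully_informative" and len(pool) < 3:
            cls = "intercross_shared"
        draw = lambda k: [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
        if cls == "both_fully_informative":
            k = 4 if len(pool) >= 4 else 3
            al = draw(k)
            dam = (al[0], al[1])
            sire = (al[2], al[3]) if k == 4 else (al[0], al[2])
        elif cls == "dam_only":
            al = draw(2)
            dam = (al[0], al[1])
            c = pool[int(rng.choice(len(pool)))]
            sire = (c, c)
        elif cls == "sire_only":
            al = draw(2)
            c = pool[int(rng.choice(len(pool)))]
            dam = (c, c)
            sire = (al[0], al[1])
        elif cls == "intercross_shared":
            al = draw(2)
            dam = (al[0], al[1])
            sire = (al[0], al[1])
        else:
            a = pool[int(rng.choice(len(pool)))]
            dam = (a, a)
            sire = (a, a)
        truth.classes[name] = cls  # record any feasibility fallback
        if rng.random() < 0.5:
            dam = (dam[1], dam[0])
        if rng.random() < 0.5:
            sire = (sire[1], sire[0])
        dam_phase[:, i] = dam
        sire_phase[:, i] = sire

    # F0 genotypes consistent with the F1 phases: haplotype 0 of each F1
    # parent traces to its grandsire, haplotype 1 to its granddam
    f0 = np.zeros((4, m, 2), dtype=np.int32)
    for i, name in enumerate(names):
        pool = truth.pools[name]
        for side, phase in ((0, dam_phase), (2, sire_phase)):
            for hap in (0, 1):
                transmitted = phase[hap, i]
                other = pool[int(rng.choice(len(pool)))]
                pair = sorted((transmitted, other))
                f0[side + hap, i] = pair
    return Founders(
        marker_names=names, f0_genotypes=f0, dam_phase=dam_phase, sire_phase=sire_phase
    )


# --------------------------------------------------------------------------
# meiosis
# --------------------------------------------------------------------------

def simulate_gametes(
    phase: np.ndarray,
    sex: str,
    truth: TruthSet,
    rng: np.random.Generator,
    n: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` gametes of a phased parent.

    Per arm, at most one crossover occurs (probability = the arm's
    sex-specific crossover probability); its position along the arm is
    uniform in cumulative-theta coordinates, so the chance of landing in an
    inter-marker interval is proportional to the interval's theta share.
    Both arms of a metacentric chromosome inherit the same centromeric
    haplotype.

    Returns ``(alleles, hap_index, crossovers)`` with shapes
    (n, n_markers), (n, n_markers), (n, n_arms).
    """
    names = truth.all_marker_names
    m = len(names)
    col = {name: i for i, name in enumerate(names)}
    alleles = np.zeros((n, m), dtype=np.int32)
    hap_idx = np.zeros((n, m), dtype=np.int8)
    crossovers = np.zeros((n, len(truth.genome.arms)), dtype=np.int8)
    arm_no = 0
    for chrom in truth.genome.chromosomes:
        start = rng.integers(0, 2, size=n).astype(np.int8)
        for arm in chrom.arms:
            p = arm.crossover_prob(sex)
            occ = rng.random(n) < p
            u = rng.random(n)  # relative crossover position along the arm
            rel = (
                arm.positions_female / arm.crossover_prob_female
                if len(arm.positions_female) and arm.crossover_prob_female > 0
                else np.zeros(len(arm.positions_female))
            )
            switch = occ[:, None] & (rel[None, :] > u[:, None])
            hap = start[:, None] ^ switch.astype(np.int8)
            idx = [col[nm] for nm in arm.marker_names]
            hap_idx[:, idx] = hap
            alleles[:, idx] = phase[hap, np.array(idx)[None, :]]
            crossovers[:, arm_no] = occ
            arm_no += 1
    return alleles, hap_idx, crossovers


def simulate_gamete(
    phase: np.ndarray, sex: str, truth: TruthSet, rng: np.random.Generator
) -> np.ndarray:
    """Single-gamete convenience wrapper: returns the allele vector."""
    alleles, _, _ = simulate_gametes(phase, sex, truth, rng, n=1)
    return alleles[0]


# --------------------------------------------------------------------------
# family assembly
# --------------------------------------------------------------------------

def simulate_family(config: SimulationConfig) -> tuple[FamilyDataset, TruthSet]:
    """Simulate a full F0/F1/F2 family under the configured design.

    The genotype table holds ``markers_total`` rows (duplicated loci as two
    rows named ``/i`` and ``/ii``); the sex locus is expressed as the
    offspring sex column, determined by the sire-transmitted allele at the
    hidden sex marker.  Missing calls are injected into F0 and F2
    genotypes at ``missing_rate``.
    """
    config.validate()
    _, rng_founders, rng_meiosis, rng_noise = _rngs(config.seed, 4)
    truth = build_truth_genome(config)
    founders = simulate_founders(truth, rng_founders)

    n_off = config.n_offspring
    dam_gam, _, _ = simulate_gametes(founders.dam_phase, "F", truth, rng_meiosis, n_off)
    sire_gam, _, _ = simulate_gametes(founders.sire_phase, "M", truth, rng_meiosis, n_off)

    names = truth.all_marker_names
    sex_col = names.index(truth.sex_marker)
    offspring_sex = np.where(sire_gam[:, sex_col] == 2, "M", "F")

    keep = [i for i, nm in enumerate(names) if nm != truth.sex_marker]
    table_names = [names[i] for i in keep]
    m = len(keep)
    n_ind = 6 + n_off
    geno = np.zeros((m, n_ind, 2), dtype=np.int32)
    geno[:, 0:4, :] = founders.f0_genotypes[:, keep, :].transpose(1, 0, 2)
    geno[:, 4, :] = founders.genotype("dam")[keep]
    geno[:, 5, :] = founders.genotype("sire")[keep]
    off = np.stack([dam_gam[:, keep], sire_gam[:, keep]], axis=2)  # (n_off, m, 2)
    geno[:, 6:, :] = off.transpose(1, 0, 2)

    if config.error_rate > 0:
        pools = [truth.pools[nm] for nm in table_names]
        err = rng_noise.random((m, n_off)) < config.error_rate
        for mi, oi in zip(*np.nonzero(err)):
            allele = pools[mi][int(rng_noise.integers(0, len(pools[mi])))]
            geno[mi, 6 + oi, int(rng_noise.integers(0, 2))] = allele
    if config.missing_rate > 0:
        f2_mask = rng_noise.random((m, n_off)) < config.missing_rate
        geno[:, 6:, :][f2_mask] = MISSING
        f0_mask = rng_noise.random((m, 4)) < config.missing_rate
        geno[:, 0:4, :][f0_mask] = MISSING
    geno.sort(axis=2)
    geno[geno[:, :, 0] == MISSING] = MISSING  # missing is all-or-nothing

    import pandas as pd

    individuals = pd.DataFrame(
        {
            "id": ["GS1", "GD1", "GS2", "GD2", "DAM", "SIRE"]
            + [f"F2-{i + 1:03d}" for i in range(n_off)],
            "generation": ["F0"] * 4 + ["F1"] * 2 + ["F2"] * n_off,
            "role": [
                "grandsire1",
                "granddam1",
                "grandsire2",
                "granddam2",
                "dam",
                "sire",
            ]
            + ["offspring"] * n_off,
            "sex": ["M", "F", "M", "F", "F", "M"] + list(offspring_sex),
        }
    )
    markers = [
        MarkerDef(
            name=nm,
            marker_class=truth.marker_class[nm],
            annotation=truth.annotations.get(nm),
        )
        for nm in table_names
    ]
    ds = FamilyDataset(individuals=individuals, markers=markers, genotypes=geno)
    return ds, truth
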