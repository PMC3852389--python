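"""Model-style front end: fit the whole linkage-mapping analysis at once.

`FamilyLinkageModel` wraps a family dataset (plus optional donor
annotations and donor karyotype) and `fit()` runs the full pipeline:
transmissions -> two-point tables -> sex-specific maps -> consensus map ->
female:male recombination comparison -> comparative inference.  The
returned `LinkageMapResults` carries the maps, the recomdif statistics and
the comparison report, offers a text `summary()`, and can `save()` all
artifacts with deterministic bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .io import DonorAnnotation, DonorChromosome, FamilyDataset, MarkerDef
from .mapping import (
    DEFAULT_FP_BUDGET,
    DEFAULT_GROUP_LOD,
    DEFAULT_ORDER_LOD,
    GenomeMap,
    TwoPointTable,
    build_consensus_map,
    build_sex_map,
)
from .comparative import comparison_report
from .twopoint import RecomDifResult, build_recomdif_pairs, recomdif


SEX_MARKER_NAME = "sex"


def ensure_sex_marker(ds: FamilyDataset) -> FamilyDataset:
    """Convert the offspring sex column into a sire-informative marker.

    The sex locus segregates like any marker heterozygous only in the
    sire: dam 1/1, sire 1/2, male offspring 1/2, female offspring 1/1.
    No-op when a marker of class ``sex`` is already present or offspring
    sexes are unrecorded.
    """
    if any(m.marker_class == "sex" for m in ds.markers):
        return ds
    sexes = ds.offspring_sex
    if not set(sexes) <= {"F", "M"} or len(set(sexes)) == 0:
        return ds
    n_ind = len(ds.individuals)
    calls = np.ones((n_ind, 2), dtype=np.int32)
    calls[ds.sire_index] = (1, 2)
    gp = ds.grandparent_indices("sire")
    if gp is not None:
        calls[gp[0]] = (1, 2)
    for k, oi in enumerate(ds.offspring_indices):
        calls[oi] = (1, 2) if sexes[k] == "M" else (1, 1)
    return ds.with_marker(MarkerDef(name=SEX_MARKER_NAME, marker_class="sex"), calls)


@dataclass
class FitConfig:
    lod_group: float = DEFAULT_GROUP_LOD
    lod_order: float = DEFAULT_ORDER_LOD
    sex_map_function: str = "haldane"
    consensus_map_function: str = "kosambi"
    min_support: int = 2
    ripple_window: int = 3
    fp_budget: float | None = DEFAULT_FP_BUDGET
    max_theta: float | None = None
    recomdif_scope: str = "consensus_group"  # pair-set filter

    def validate(self) -> None:
        if self.lod_group <= 0 or self.lod_order <= 0:
            raise ValueError("LOD thresholds must be positive")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.ripple_window < 2:
            raise ValueError("ripple window must be >= 2")


class FamilyLinkageModel:
    """Linkage-mapping model for one outbred three-generation family."""

    def __init__(
        self,
        dataset: FamilyDataset,
        annotations: dict[str, DonorAnnotation] | None = None,
        donor_karyotype: dict[str, DonorChromosome] | None = None,
        use_sex_column: bool = True,
    ) -> None:
        if use_sex_column:
            dataset = ensure_sex_marker(dataset)
        if annotations:
            dataset = dataset.annotate(annotations)
        self.dataset = dataset
        self.annotations = annotations or {
            m.name: m.annotation for m in dataset.markers if m.annotation is not None
        }
        self.donor_karyotype = donor_karyotype

    @classmethod
    def from_files(
        cls,
        genotypes_path,
        annotations_path=None,
        donor_karyotype_path=None,
        mendel: str = "mask",
    ) -> "FamilyLinkageModel":
        ds = fio.read_genotypes(genotypes_path, mendel=mendel)
        annotations = (
            fio.read_annotations(annotations_path) if annotations_path else None
        )
        donor = (
            fio.read_donor_karyotype(donor_karyotype_path)
            if donor_karyotype_path
            else None
        )
        return cls(ds, annotations=annotations, donor_karyotype=donor)

    def fit(self, config: FitConfig | None = None, **overrides) -> "LinkageMapResults":
        config = config or FitConfig()
        for key, val in overrides.items():
            if not hasattr(config, key):
                raise TypeError(f"unknown fit option {key!r}")
            setattr(config, key, val)
        config.validate()
        ds = self.dataset
        female_table = TwoPointTable.from_parent(ds, "dam")
        male_table = TwoPointTable.from_parent(ds, "sire")
        female_map = build_sex_map(
            ds,
            "dam",
            map_fn=config.sex_map_function,
            lod_group=config.lod_group,
            lod_order=config.lod_order,
            fp_budget=config.fp_budget,
            max_theta=config.max_theta,
            ripple_window=config.ripple_window,
            table=female_table,
        )
        male_map = build_sex_map(
            ds,
            "sire",
            map_fn=config.sex_map_function,
            lod_group=config.lod_group,
            lod_order=config.lod_order,
            fp_budget=config.fp_budget,
            max_theta=config.max_theta,
            ripple_window=config.ripple_window,
            table=male_table,
        )
        consensus = build_consensus_map(
            ds,
            female_map,
            male_map,
            female_table,
            male_table,
            map_fn=config.consensus_map_function,
            lod_order=config.lod_order,
            ripple_window=config.ripple_window,
        )
        pair_groups = [g.all_markers for g in consensus.groups]
        pair_table = build_recomdif_pairs(
            ds,
            pair_groups,
            (female_table.names, _codes_for(ds, "dam")),
            (male_table.names, _codes_for(ds, "sire")),
        )
        recom = recomdif(pair_table) if len(pair_table) else None
        report = None
        if self.annotations:
            report = comparison_report(
                consensus,
                self.annotations,
                self.donor_karyotype,
                ds.markers,
                min_support=config.min_support,
                extra_maps={"female": female_map},
            )
        return LinkageMapResults(
            model=self,
            config=config,
            female_table=female_table,
            male_table=male_table,
            female_map=female_map,
            male_map=male_map,
            consensus_map=consensus,
            recomdif=recom,
            comparison=report,
        )


def _codes_for(ds: FamilyDataset, parent: str):
    from .twopoint import transmission_matrix

    return transmission_matrix(ds, parent)[1]


@dataclass
class LinkageMapResults:
    """Fitted maps, recombination-sex comparison and comparative report."""

    model: FamilyLinkageModel
    config: FitConfig
    female_table: TwoPointTable
    male_table: TwoPointTable
    female_map: GenomeMap
    male_map: GenomeMap
    consensus_map: GenomeMap
    recomdif: RecomDifResult | None
    comparison: dict | None

    def summary(self) -> str:
        c = self.consensus_map
        lines = [
            "Family linkage analysis",
            "=======================",
            f"offspring meioses per parent : {self.model.dataset.n_offspring}",
            f"markers in dataset           : {len(self.model.dataset.markers)}",
            f"linkage groups (consensus)   : {len(c.groups)}",
            f"markers mapped (consensus)   : {c.marker_count}"
            + (f" (+{len(c.dropped)} dropped as unstable)" if c.dropped else ""),
            f"unassigned markers           : {len(c.unassigned)}",
            f"female map ({self.female_map.map_function:>8}) : "
            f"{self.female_map.total_length:8.1f} cM over {self.female_map.marker_count} markers",
            f"male map   ({self.male_map.map_function:>8}) : "
            f"{self.male_map.total_length:8.1f} cM over {self.male_map.marker_count} markers",
            f"consensus  ({c.map_function:>8}) : {c.total_length:8.1f} cM",
        ]
        if self.recomdif is not None:
            r = self.recomdif
            lines += [
                f"female:male recombination    : {r.ratio:.2f} "
                f"(range {r.ratio_range[0]:.2f}-{r.ratio_range[1]:.2f}, n = {r.n_pairs} pairs)",
                f"G-test (pooled 2x2)          : G = {r.g:.1f}, df = {r.df}, "
                f"p = {r.p_value:.3g}",
            ]
        if self.comparison is not None and "summary" in self.comparison:
            s = self.comparison["summary"]
            lines += [
                f"structure calls              : {s['n_metacentric']} metacentric, "
                f"{s['n_acrocentric']} acrocentric, {s['n_unresolved']} unresolved",
                f"haploid arm number           : {s['haploid_arm_number']}",
                f"conserved chromosomes        : {s['n_conserved']}",
                f"homeologous group pairings   : {len(self.comparison['homeologs'])}",
            ]
        elif self.comparison is not None:
            lines += [
                f"homeologous group pairings   : {len(self.comparison['homeologs'])}",
            ]
        return "\n".join(lines)

    def run_log(self) -> dict:
        log = {
            "config": asdict(self.config),
            "n_offspring": self.model.dataset.n_offspring,
            "n_markers": len(self.model.dataset.markers),
            "stages": {
                "female_map": {
                    "groups": len(self.female_map.groups),
                    "markers": self.female_map.marker_count,
                    "length_cM": self.female_map.total_length,
                    "unassigned": len(self.female_map.unassigned),
                },
                "male_map": {
                    "groups": len(self.male_map.groups),
                    "markers": self.male_map.marker_count,
                    "length_cM": self.male_map.total_length,
                    "unassigned": len(self.male_map.unassigned),
                },
                "consensus_map": {
                    "groups": len(self.consensus_map.groups),
                    "markers": self.consensus_map.marker_count,
                    "length_cM": self.consensus_map.total_length,
                    "dropped": self.consensus_map.dropped,
                    "unassigned": len(self.consensus_map.unassigned),
                },
            },
        }
        if self.recomdif is not None:
            log["stages"]["recomdif"] = {
                "ratio": self.recomdif.ratio,
                "n_pairs": self.recomdif.n_pairs,
                "g": self.recomdif.g,
                "p_value": self.recomdif.p_value,
            }
        return log

    def save(self, out_dir) -> list[str]:
        """Write all artifacts (map TSVs, recomdif table, comparison report,
        run log) into ``out_dir``; returns the file names written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, gmap in (
            ("map_female.tsv", self.female_map),
            ("map_male.tsv", self.male_map),
            ("map_consensus.tsv", self.consensus_map),
        ):
            fio.write_map(gmap, out / name)
            written.append(name)
        fio.write_mapchart(self.consensus_map, out / "map_consensus_chart.txt")
        written.append("map_consensus_chart.txt")
        if self.recomdif is not None:
            df = self.recomdif.pairs.copy()
            df.to_csv(out / "recomdif_pairs.tsv", sep="\t", index=False)
            written.append("recomdif_pairs.tsv")
        if self.comparison is not None:
            fio.write_report(self.comparison, out / "comparison_report.json")
            written.append("comparison_report.json")
        fio.write_report(self.run_log(), out / "run_log.json")
        written.append("run_log.json")
        return written
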