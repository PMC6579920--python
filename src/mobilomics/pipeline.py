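"""End-to-end orchestration: genome IO -> pan-genome -> IS -> HGT -> ICE.

The pipeline is a thin sequencing of the library stages with file output.
Every threshold is surfaced as a named configuration key with the
documented default; re-running with an identical configuration and inputs
reproduces identical summary values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .genomes import (
    Genome,
    gc_content,
    normalize_to_ori,
    read_genome,
    write_gff3,
)
from .hgt import classify_hgt_regions, cross_species_regions, map_plasmid_integration
from .ice import (
    Primer,
    find_island_boundaries,
    predict_excision_pcr,
    screen_signature_genes,
)
from .insertion_sequences import (
    build_is_library,
    detect_composite_transposons,
    detect_gene_disruption,
    is_census,
    mobile_annotation_counts,
)
from .pangenome import build_profile, orfan_positions

log = logging.getLogger("mobilomics")

ALL_STAGES = ("pangenome", "is", "hgt", "ice")

DEFAULT_THRESHOLDS = {
    "cluster_identity": 0.60,
    "cluster_coverage": 0.75,
    "hgt_min_length": 2000,
    "hgt_min_identity": 0.90,
    "hgt_merge_gap": 1000,
    "is_flank": 1000,
    "is_min_identity": 0.90,
    "is_min_span": 0.80,
    "max_cargo": 20000,
    "min_tpase_identity": 0.60,
    "min_ir_identity": 0.60,
    "plasmid_min_identity": 0.95,
    "att_repeat_length": 12,
    "orfan_window": 50000,
}


@dataclass
class RunConfig:
    genomes: list[dict]  # {"path":..., "species":..., "strain":...(opt)}
    stages: tuple[str, ...] = ALL_STAGES
    focal_species: str | None = None  # pan-genome / HGT-recipient species
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    ice_seeds: list[dict] = field(default_factory=list)  # {"strain","start","end"}
    primers: list[dict] = field(default_factory=list)  # {"name","sequence"}
    normalize_ori: bool = True
    outdir: str = "mobilomics_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(data.pop("thresholds", {}))
        return cls(thresholds=thresholds, **data)

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("run config lists no genomes")
        for k, v in self.thresholds.items():
            if k not in DEFAULT_THRESHOLDS:
                raise ValueError(f"unknown threshold {k}")
            if isinstance(DEFAULT_THRESHOLDS[k], float) and not 0 <= float(v) <= 1:
                raise ValueError(f"threshold {k}={v} outside [0, 1]")
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def load_genomes(config: RunConfig) -> list[Genome]:
    genomes = []
    for spec in config.genomes:
        path = Path(spec["path"])
        g = read_genome(path, strain=spec.get("strain"), species_label=spec.get("species", ""))
        log.info("loaded %s (%s, sha1 %s)", g.strain, path.name, _sha1(path))
        if config.normalize_ori:
            try:
                g = normalize_to_ori(g)
            except Exception as exc:
                log.warning("%s: ori normalization skipped (%s)", g.strain, exc)
        genomes.append(g)
    return genomes


def run_pipeline(config: RunConfig, genomes: list[Genome] | None = None) -> dict:
    """Execute the toggled stages and write TSV/GFF3/JSON artifacts.

    Returns the machine-readable summary (also written to summary.json).
    """
    config.validate()
    t = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = load_genomes(config)
    focal = [
        g for g in genomes
        if config.focal_species is None or g.species_label == config.focal_species
    ]
    partners = [g for g in genomes if g not in focal]
    summary: dict = {"version": __version__, "seed": config.seed, "genomes": {}}
    for g in genomes:
        counts = mobile_annotation_counts(g)
        chrom = g.chromosome
        summary["genomes"][g.strain] = {
            "species": g.species_label,
            "chromosome_length": len(chrom.sequence),
            "gc_percent": round(gc_content(chrom), 2),
            "cds": sum(1 for _, f in g.all_features() if f.kind == "CDS"),
            "rRNA": sum(1 for _, f in g.all_features() if f.kind == "rRNA"),
            "tRNA": sum(1 for _, f in g.all_features() if f.kind == "tRNA"),
            **counts,
        }
        write_gff3(g, outdir / f"{g.strain}.gff3")

    timings = {}
    if "pangenome" in config.stages:
        t0 = time.time()
        try:
            profile = build_profile(
                focal,
                min_identity=t["cluster_identity"],
                min_coverage=t["cluster_coverage"],
                seed=config.seed,
            )
        except Exception as exc:
            raise StageError("pangenome", exc)
        rows = []
        for c in profile.clusters:
            for strain, locus in c.members:
                rows.append(
                    f"{c.cluster_id}\t{strain}\t{locus}\t{int((strain, locus) == c.centroid)}"
                )
        (outdir / "clusters.tsv").write_text(
            "cluster_id\tgenome\tlocus_tag\tis_centroid\n" + "\n".join(rows) + "\n"
        )
        profile.matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        profile.pan_curve.to_csv(outdir / "pan_curve.tsv", sep="\t")
        profile.core_curve.to_csv(outdir / "core_curve.tsv", sep="\t")
        profile.spectrum.to_csv(outdir / "k_spectrum.tsv", sep="\t")
        n = profile.matrix.shape[1]
        positions = orfan_positions(focal, profile.orfans, window=int(t["orfan_window"]))
        with open(outdir / "orfan_positions.tsv", "w") as fh:
            fh.write("genome\twindow_start\torfans\n")
            for strain, series in positions.items():
                for w, c in series.items():
                    fh.write(f"{strain}\t{w}\t{c}\n")
        summary["pangenome"] = {
            "pan_clusters": int(len(profile.clusters)),
            "core_clusters": int(profile.spectrum.get(n, 0)),
            "orfan_genes": int(len(profile.orfans)),
            "k_spectrum": {int(k): int(v) for k, v in profile.spectrum.items()},
        }
        timings["pangenome"] = round(time.time() - t0, 2)

    library = []
    census_copies: dict = {}
    if "is" in config.stages:
        t0 = time.time()
        try:
            library, _ = build_is_library(
                genomes,
                flank=int(t["is_flank"]),
                min_identity=t["is_min_identity"],
                min_span=t["is_min_span"],
            )
            full, partial, census_copies = is_census(
                library, genomes, min_identity=t["is_min_identity"], min_span=t["is_min_span"]
            )
            all_copies = [c for name in census_copies for c in census_copies[name]]
            disruptions = detect_gene_disruption(all_copies, genomes)
            composites = detect_composite_transposons(
                all_copies,
                genomes,
                {e.name: e for e in library},
                max_cargo=int(t["max_cargo"]),
                min_tpase_identity=t["min_tpase_identity"],
                min_ir_identity=t["min_ir_identity"],
            )
        except Exception as exc:
            raise StageError("is", exc)
        with open(outdir / "is_library.fasta", "w") as fh:
            for e in library:
                fh.write(f">{e.name} length={e.length}\n{e.element_sequence}\n")
        with open(outdir / "is_library.tsv", "w") as fh:
            fh.write("name\tlength\tleft_ir\tright_ir\tsource_genome\ttransposase_locus\n")
            for e in library:
                fh.write(
                    f"{e.name}\t{e.length}\t{e.left_ir}\t{e.right_ir}\t"
                    f"{e.source_genome}\t{e.transposase_locus[1]}\n"
                )
        full.to_csv(outdir / "is_census.tsv", sep="\t")
        partial.to_csv(outdir / "is_census_partial.tsv", sep="\t")
        with open(outdir / "is_disruptions.tsv", "w") as fh:
            fh.write("genome\tlocus_tag\tproduct\telement\tcopy_start\tcopy_end\toffset\n")
            for d in disruptions:
                fh.write(
                    f"{d.genome}\t{d.locus_tag}\t{d.product}\t{d.element_name}\t"
                    f"{d.copy_start}\t{d.copy_end}\t{d.insertion_offset}\n"
                )
        with open(outdir / "composite_transposons.tsv", "w") as fh:
            fh.write(
                "genome\tleft_element\tleft_start\tright_end\tcargo_start\tcargo_end\t"
                "tpase_identity\tir_identity\tcargo_genes\n"
            )
            for c in composites:
                fh.write(
                    f"{c.left.genome}\t{c.left.element_name}\t{c.left.start}\t{c.right.end}\t"
                    f"{c.cargo_start}\t{c.cargo_end}\t{c.transposase_identity:.3f}\t"
                    f"{c.ir_cross_identity:.3f}\t{','.join(c.cargo_genes)}\n"
                )
        summary["is"] = {
            "elements": int(len(library)),
            "census": {e: {s: int(v) for s, v in row.items()} for e, row in full.T.to_dict().items()},
            "disruptions": int(len(disruptions)),
            "composite_transposons": int(len(composites)),
        }
        timings["is"] = round(time.time() - t0, 2)

    regions = []
    if "hgt" in config.stages:
        t0 = time.time()
        try:
            for g in focal:
                regions.extend(
                    cross_species_regions(
                        g,
                        partners,
                        min_length=int(t["hgt_min_length"]),
                        min_identity=t["hgt_min_identity"],
                        merge_gap=int(t["hgt_merge_gap"]),
                    )
                )
            table = classify_hgt_regions(regions)
            plasmids = [r for g in genomes for r in g.plasmids]
            plasmid_maps = {
                p.replicon_id: map_plasmid_integration(
                    p, focal, min_identity=t["plasmid_min_identity"]
                )
                for p in plasmids
            }
        except Exception as exc:
            raise StageError("hgt", exc)
        with open(outdir / "hgt_regions.tsv", "w") as fh:
            fh.write(
                "recipient\tstart\tend\tlength\tpartner\tpartner_species\tidentity\tgenes\n"
            )
            for r in regions:
                fh.write(
                    f"{r.recipient}\t{r.start}\t{r.end}\t{r.length}\t{r.partner}\t"
                    f"{r.partner_species}\t{r.identity:.4f}\t"
                    f"{','.join(l for l, _, _ in r.genes)}\n"
                )
        table.to_csv(outdir / "hgt_categories.tsv", sep="\t", index=False)
        with open(outdir / "plasmid_coverage.tsv", "w") as fh:
            fh.write("plasmid\tgenome\tcoverage_fraction\tn_fragments\tintervals\n")
            for pid, maps in plasmid_maps.items():
                for strain, m in maps.items():
                    ivals = ";".join(f"{s}-{e}" for s, e in m.covered_intervals)
                    fh.write(
                        f"{pid}\t{strain}\t{m.coverage_fraction:.4f}\t{m.n_fragments}\t{ivals}\n"
                    )
        summary["hgt"] = {
            "regions": int(len(regions)),
            "largest_region_bp": int(max((r.length for r in regions), default=0)),
            "hgt_genes": int(table["genes"].sum()) if len(table) else 0,
            "category_counts": {
                row["category"]: int(row["genes"]) for _, row in table.iterrows()
            },
            "plasmid_coverage": {
                pid: {s: round(m.coverage_fraction, 4) for s, m in maps.items()}
                for pid, maps in plasmid_maps.items()
            },
        }
        timings["hgt"] = round(time.time() - t0, 2)

    if "ice" in config.stages:
        t0 = time.time()
        islands = []
        try:
            by_strain = {g.strain: g for g in genomes}
            seeds = [(s["strain"], (int(s["start"]), int(s["end"]))) for s in config.ice_seeds]
            if not seeds:  # fall back to large HGT regions as island seeds
                seeds = [
                    (r.recipient, (r.start, r.end)) for r in regions if r.length >= 20000
                ]
            primers = [Primer(p["name"], p["sequence"]) for p in config.primers]
            for strain, seed in seeds:
                g = by_strain[strain]
                island = find_island_boundaries(
                    g, seed, repeat_length=int(t["att_repeat_length"])
                )
                screen_signature_genes(island, g)
                if island.bounded and primers:
                    predict_excision_pcr(g, island, primers)
                islands.append(island)
        except Exception as exc:
            raise StageError("ice", exc)
        with open(outdir / "ice_islands.tsv", "w") as fh:
            fh.write(
                "genome\tstart\tend\tlength\tatt\tbounded\tintegration_excision\t"
                "replication\tconjugation\n"
            )
            for i in islands:
                sig = i.signature_hits
                fh.write(
                    f"{i.genome}\t{i.start}\t{i.end}\t{i.length}\t{i.att_repeat}\t"
                    f"{int(i.bounded)}\t{len(sig.get('integration_excision', []))}\t"
                    f"{len(sig.get('replication', []))}\t{len(sig.get('conjugation', []))}\n"
                )
        summary["ice"] = {
            "islands": int(len(islands)),
            "bounded": int(sum(i.bounded for i in islands)),
            "islands_detail": [
                {
                    "genome": i.genome,
                    "start": int(i.start),
                    "end": int(i.end),
                    "att": i.att_repeat,
                    "signature_counts": {k: len(v) for k, v in i.signature_hits.items()},
                }
                for i in islands
            ],
        }
        timings["ice"] = round(time.time() - t0, 2)

    summary["timings_s"] = timings
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(asdict(config)))
    return summary
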