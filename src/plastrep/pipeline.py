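"""Survey orchestration: scan -> large IR -> association -> profiles -> stats.

A run is driven by a manifest (one genome per row: path, format, annotation,
group), writes one TSV/GFF3 bundle per genome plus panel-level tables, and
records its resolved configuration and seed so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .association import DEFAULT_GENE_SET, associate, conservation_table
from .genome import AnnotatedGenome, Group, genome_summary
from .genome_io import read_genome, write_repeats
from .gene_order import genome_rearrangement_distance
from .large_ir import analyze_large_ir
from .lineage_stats import lineage_comparison
from .small_repeats import IRParams, TRParams, find_inverted_repeats, find_tandem_repeats, repeat_profile


@dataclass
class RunConfig:
    manifest: list[dict]  # rows: {path, format, gff3, group, id}
    out_dir: str
    seed: int = 0
    ir_params: IRParams = field(default_factory=IRParams)
    tr_params: TRParams = field(default_factory=TRParams)
    search_distance: int = 300
    genes: tuple[str, ...] = DEFAULT_GENE_SET
    groups_for_fisher: tuple[str, str] = ("CASH", "green")
    rearrangements: bool = True

    def validate(self):
        for row in self.manifest:
            if not Path(row["path"]).exists():
                raise FileNotFoundError(row["path"])
        self.ir_params.validate()
        self.tr_params.validate()


def read_manifest(path) -> list[dict]:
    """TSV manifest: path [format] [gff3] [group] [id]; '-' means unset."""
    rows = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            row = row + ["-"] * (5 - len(row))
            rows.append(
                {
                    "path": row[0],
                    "format": None if row[1] in ("-", "") else row[1],
                    "gff3": None if row[2] in ("-", "") else row[2],
                    "group": "other" if row[3] in ("-", "") else row[3],
                    "id": None if row[4] in ("-", "") else row[4],
                }
            )
    return rows


def _write_tsv(path, header, rows):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        w.writerows(rows)


def run_survey(config: RunConfig) -> dict:
    """Run the full survey; returns a summary dict (also written as JSON).

    Genomes failing validation are recorded and skipped; their count is
    reported in the manifest summary and the exit status of the CLI.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes: list[AnnotatedGenome] = []
    failures: list[dict] = []
    for row in config.manifest:
        try:
            g = read_genome(row["path"], row["format"], group=Group(row["group"]),
                            gff3=row["gff3"])
            if row["id"]:
                g.id = row["id"]
            genomes.append(g)
        except Exception as exc:  # recorded, not fatal
            failures.append({"path": row["path"], "error": str(exc)})

    profiles = []
    panel = []
    ir_rows = []
    assoc_rows = []
    for g in genomes:
        irs = find_inverted_repeats(g, config.ir_params)
        trs = find_tandem_repeats(g, config.tr_params)
        write_repeats(irs + trs, out / f"{g.id}.repeats.tsv", "tsv", genome_id=g.id)
        write_repeats(irs + trs, out / f"{g.id}.repeats.gff3", "gff3", genome_id=g.id)
        profiles.append(repeat_profile(g, irs, trs))
        panel.append((g, irs + trs))
        report = analyze_large_ir(g)
        if report.present:
            div = report.per_gene_divergence
            s23 = div.get("23S", (None, None))
            s16 = div.get("16S", (None, None))
            ir_rows.append([g.id, s23[0], s23[1], s16[0], s16[1],
                            report.ir_length, report.isr_label or ""])
        else:
            ir_rows.append([g.id, "No Inverted Repeat", "", "", "", "", ""])
        for a in associate(g, irs + trs, config.search_distance):
            assoc_rows.append([a.genome, a.gene, a.repeat_type, a.distance, a.gene_end])

    _write_tsv(out / "large_ir.tsv",
               ["genome", "snps_23S", "indels_23S", "snps_16S", "indels_16S",
                "ir_length", "isr_label"], ir_rows)
    _write_tsv(out / "associations.tsv",
               ["genome", "gene", "repeat_type", "distance", "gene_end"], assoc_rows)
    _write_tsv(
        out / "profiles.tsv",
        ["genome", "group", "n_inverted", "n_tandem", "mean_repeat_size",
         "max_repeat_size", "genome_size", "mean_intergenic"],
        [
            [p.genome_id, p.group.value, p.n_inverted, p.n_tandem,
             "" if p.mean_repeat_size is None else f"{p.mean_repeat_size:.2f}",
             "" if p.max_repeat_size is None else p.max_repeat_size,
             p.genome_size,
             "" if p.mean_intergenic is None else f"{p.mean_intergenic:.2f}"]
            for p in profiles
        ],
    )

    cons = conservation_table(panel, config.genes, config.search_distance)
    _write_tsv(
        out / "conservation.tsv",
        ["gene", "carrying", "with_repeat", "fraction", "flag"],
        [
            [gene, row["carrying"], row["with_repeat"],
             "" if row["fraction"] is None else f"{row['fraction']:.4f}", row["flag"]]
            for gene, row in cons.items()
        ],
    )

    stats_rows = []
    ga, gb = config.groups_for_fisher
    try:
        cmp_ = lineage_comparison(profiles, ga, gb)
        stats_rows.append(["fisher_p", f"{cmp_.fisher_p:.6g}", f"{ga} vs {gb}"])
        for key, reg in sorted(cmp_.regressions.items()):
            stats_rows.append(
                [f"ols_{key[0]}_vs_{key[1]}_{key[2]}",
                 f"slope={reg.slope:.6g};r2={reg.r_squared:.4f};p={reg.p_value:.4g}",
                 f"n={reg.n}"]
            )
    except ValueError as exc:
        stats_rows.append(["stats_skipped", str(exc), ""])
    _write_tsv(out / "stats.tsv", ["statistic", "value", "detail"], stats_rows)

    rearr_rows = []
    if config.rearrangements and len(genomes) >= 2:
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                try:
                    res = genome_rearrangement_distance(genomes[i], genomes[j])
                    rearr_rows.append([genomes[i].id, genomes[j].id, res.distance,
                                       res.breakpoints, res.hurdles, res.fortress])
                except ValueError as exc:
                    rearr_rows.append([genomes[i].id, genomes[j].id, "", "", "", str(exc)])
        _write_tsv(out / "rearrangements.tsv",
                   ["genome_a", "genome_b", "reversal_distance", "breakpoints",
                    "hurdles", "fortress"], rearr_rows)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_genomes": len(genomes),
        "n_failed": len(failures),
        "failures": failures,
        "ir_params": dataclasses.asdict(config.ir_params),
        "tr_params": dataclasses.asdict(config.tr_params),
        "search_distance": config.search_distance,
        "genes": list(config.genes),
        "genome_summaries": [genome_summary(g) for g in genomes],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
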