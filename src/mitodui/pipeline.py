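"""Full-analysis orchestration: architecture -> composition -> divergence ->
coding potential -> control region -> gene order, written as TSV tables plus
a JSON summary.

Stages are isolated: a failure in one stage is logged into the report and
the remaining independent stages still run.  With a fixed config and seed
the JSON summary is byte-identical between runs (timestamps live only in
the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import composition as comp_mod
from . import divergence as div_mod
from .coding_potential import testcode
from .gene_order import breakpoint_distance, extract_order
from .genome import (MitoGenome, cox2_extension, gene_overlaps, gene_table,
                     intergenic_regions, load_genome, start_codon_census)
from .repeats import control_region_candidates

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    f_path: str | None = None           # None => packaged synthetic fixture
    m_path: str | None = None
    format: str | None = None
    code: int = 5
    bootstrap: int = 1000
    seed: int = 42
    min_period: int = 20
    min_copies: float = 2.0
    min_identity: float = 0.85
    scope: str = "pcg-rrna"
    out_dir: str = "mitodui-report"

    def validate(self) -> None:
        if self.bootstrap < 100:
            raise ValueError("bootstrap must be >= 100")
        if self.scope not in ("pcg-rrna", "all"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


def _load_pair(config: RunConfig) -> tuple[MitoGenome, MitoGenome]:
    if config.f_path is None or config.m_path is None:
        from .data import solenaia_fixture_pair
        return solenaia_fixture_pair()
    return (load_genome(config.f_path, config.format, sex_type="F"),
            load_genome(config.m_path, config.format, sex_type="M"))


def _tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_report(config: RunConfig) -> dict:
    """Run every stage on the F/M genome pair and write the report bundle.

    Returns the JSON summary (also written to ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mitodui")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict = {"schema_version": SCHEMA_VERSION, "config": asdict(config),
                     "errors": {}}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:   # stage isolation
                log.error("stage %s failed: %s", name, exc)
                summary["errors"][name] = f"{type(exc).__name__}: {exc}"
        return deco

    f, m = _load_pair(config)
    genomes = {"F": f, "M": m}
    summary["genomes"] = {k: {"identifier": g.identifier, "length": g.length,
                              "n_features": len(g.features)}
                          for k, g in genomes.items()}

    @stage("architecture")
    def _architecture():
        arch = {}
        rows = []
        for key, g in genomes.items():
            table = gene_table(g, config.code)
            regions = intergenic_regions(g)
            overlaps = gene_overlaps(g)
            largest = max(regions, key=lambda r: r.length)
            arch[key] = {
                "n_pcg": sum(1 for x in g.features if x.kind == "PCG"),
                "n_orf": sum(1 for x in g.features if x.kind == "ORF"),
                "n_trna": sum(1 for x in g.features if x.kind == "tRNA"),
                "n_rrna": sum(1 for x in g.features if x.kind == "rRNA"),
                "n_unassigned": len(regions),
                "largest_unassigned_bp": largest.length,
                "largest_unassigned_flanks":
                    [largest.flank_upstream, largest.flank_downstream],
                "n_overlaps": len(overlaps),
                "max_overlap_bp": max((o.overlap_length for o in overlaps),
                                      default=0),
                "start_codon_census": start_codon_census(table),
            }
            rows += [[key, r.label, r.length, r.start_codon, r.stop_codon,
                      r.start_class] for r in table]
            _tsv(out / f"overlaps_{key}.tsv", ["gene_a", "gene_b", "bp"],
                 [[o.gene_a, o.gene_b, o.overlap_length] for o in overlaps])
        _tsv(out / "gene_table.tsv",
             ["genome", "gene", "length_bp", "start", "stop", "start_class"],
             rows)
        ext_bp, ext_frac = cox2_extension(f, m)
        arch["cox2_extension_bp"] = ext_bp
        arch["cox2_extension_pct"] = round(100 * ext_frac, 1)
        summary["architecture"] = arch

    @stage("composition")
    def _composition():
        comp = {}
        rows = []
        for key, g in genomes.items():
            table = comp_mod.partition_stats(g)
            comp[key] = {part: {"at_pct": round(s.at_pct, 1),
                                "gc_pct": round(s.gc_pct, 1),
                                "at_skew": round(s.at_skew, 2),
                                "gc_skew": round(s.gc_skew, 2)}
                         for part, s in table.items()}
            rows += [[key, part, f"{s.at_pct:.1f}", f"{s.gc_pct:.1f}",
                      f"{s.at_skew:.2f}", f"{s.gc_skew:.2f}"]
                     for part, s in table.items()]
            cds = [g.extract(x) for x in g.features if x.kind == "PCG"]
            usage = comp_mod.codon_usage(cds, config.code)
            comp[key]["most_frequent_codon"] = usage.as_rna(usage.most_frequent)
            rscu = usage.rscu()
            _tsv(out / f"codon_usage_{key}.tsv",
                 ["codon", "count", "rscu"],
                 [[usage.as_rna(c), usage.counts.get(c, 0),
                   f"{rscu[c]:.3f}"] for c in sorted(rscu)])
        _tsv(out / "composition.tsv",
             ["genome", "partition", "AT%", "GC%", "AT_skew", "GC_skew"], rows)
        summary["composition"] = comp

    @stage("divergence")
    def _divergence():
        results = div_mod.gene_divergence(
            f, m, code=config.code,
            bootstrap_replicates=config.bootstrap, seed=config.seed)
        rows = []
        div = {}
        for r in results:
            rows.append([r.gene, f"{r.pd_nt:.3f}", f"{r.pd_nt_se:.3f}",
                         "NA" if r.pd_aa is None else f"{r.pd_aa:.3f}",
                         "NA" if r.pd_aa_se is None else f"{r.pd_aa_se:.3f}",
                         "NA" if r.ka is None else f"{r.ka:.4f}",
                         "NA" if r.ks is None else f"{r.ks:.4f}",
                         "NA" if r.omega is None else f"{r.omega:.4f}"])
            div[r.gene] = {"pd_nt": r.pd_nt, "pd_nt_se": r.pd_nt_se,
                           "pd_aa": r.pd_aa, "pd_aa_se": r.pd_aa_se,
                           "ka": r.ka, "ks": r.ks, "omega": r.omega}
        # concatenated protein-coding dataset (gender-specific ORFs excluded)
        alns = []
        names = []
        for x in f.features:
            if x.kind != "PCG":
                continue
            try:
                m.feature(x.label)
            except KeyError:
                continue
            alns.append(div_mod.pairwise_codon_alignment(
                f.extract(x.label), m.extract(x.label),
                labels=(f.identifier, m.identifier), code=config.code))
            names.append(x.label)
        if alns:
            concat, parts = div_mod.concat_and_mask(alns, names=names)
            div["all_proteins"] = {
                "pd_nt": div_mod.p_distance(concat, "nt"),
                "pd_aa": div_mod.p_distance(div_mod.aa_rows(concat), "aa"),
                "columns_nt": concat.length,
            }
            ng = div_mod.nei_gojobori(concat)
            div["all_proteins"].update(ka=ng.ka, ks=ng.ks, omega=ng.omega)
            rows.append(["all_proteins",
                         f"{div['all_proteins']['pd_nt']:.3f}", "",
                         f"{div['all_proteins']['pd_aa']:.3f}", "",
                         f"{ng.ka:.4f}", f"{ng.ks:.4f}",
                         "NA" if ng.omega is None else f"{ng.omega:.4f}"])
            with open(out / "partitions.txt", "w") as fh:
                for gname, (a, b) in parts.items():
                    fh.write(f"DNA, {gname} = {a + 1}-{b}\n")
        _tsv(out / "divergence.tsv",
             ["gene", "pd_nt", "se_nt", "pd_aa", "se_aa", "Ka", "Ks", "Ka/Ks"],
             rows)
        summary["divergence"] = div

    @stage("coding_potential")
    def _coding_potential():
        tc = {}
        rows = []
        for key, g in genomes.items():
            for x in g.features:
                if x.kind != "ORF":
                    continue
                cds = g.extract(x)
                res = testcode(cds[:-3])   # stop codon excluded
                tc[x.label] = {"score": res.score, "verdict": res.verdict,
                               "probability_coding": res.probability_coding}
                rows.append([key, x.label, res.score, res.verdict,
                             res.probability_coding])
        _tsv(out / "testcode.tsv",
             ["genome", "orf", "score", "verdict", "prob_coding_pct"], rows)
        summary["coding_potential"] = tc

    @stage("control_region")
    def _control_region():
        cr = {}
        rows = []
        for key, g in genomes.items():
            cands = control_region_candidates(
                g, min_period=config.min_period, min_copies=config.min_copies,
                min_identity=config.min_identity)
            for rank, c in enumerate(cands[:10], 1):
                rep = c.repeats[0] if c.repeats else None
                rows.append([key, rank,
                             f"{c.region.flank_upstream}-{c.region.flank_downstream}",
                             c.length, f"{c.at_pct:.1f}",
                             rep.period if rep else "NA",
                             rep.copies if rep else "NA",
                             c.best_hairpin.stem if c.best_hairpin else 0,
                             int(c.has_stemloop_repeat), f"{c.score:.3f}"])
            top = cands[0]
            rep = top.repeats[0] if top.repeats else None
            cr[key] = {
                "flanks": [top.region.flank_upstream,
                           top.region.flank_downstream],
                "length": top.length, "at_pct": round(top.at_pct, 1),
                "repeat_period": rep.period if rep else None,
                "repeat_copies": rep.copies if rep else None,
                "has_stemloop_repeat": top.has_stemloop_repeat,
            }
        _tsv(out / "cr_candidates.tsv",
             ["genome", "rank", "flanks", "length", "AT%", "period", "copies",
              "stem", "stemloop_ok", "score"], rows)
        summary["control_region"] = cr

    @stage("gene_order")
    def _gene_order():
        orders = {k: extract_order(g, config.scope)
                  for k, g in genomes.items()}
        with open(out / "gene_orders.txt", "w") as fh:
            for k, o in orders.items():
                fh.write(f"{k}\t{o}\n")
        summary["gene_order"] = {
            "F": str(orders["F"]), "M": str(orders["M"]),
            "breakpoint_distance":
                breakpoint_distance(orders["F"], orders["M"])
                if orders["F"].labels == orders["M"].labels else None,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    root.removeHandler(handler)
    handler.close()
    return summary
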