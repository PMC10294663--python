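"""End-to-end orchestration: simulate -> ingest -> enrich -> curate -> profile.

One :class:`RunConfig` (usually loaded from YAML) drives a fully
reproducible run.  Every stage writes its outputs before the next starts,
all thresholds are echoed into ``report.json``, and the final candidate
table is the join the screen is for: genes flagged enriched among
spore-host phages AND not ruled out as bacterial contamination by scaffold
curation ("possible viral" genes are kept but flagged; strictness is
configurable via ``require_likely_viral``).

Outputs are deterministic for a fixed config+seed: data tables carry no
timestamps or absolute paths (wall-clock information goes to ``run.log``
only), so two runs of the same config are byte-identical apart from the
log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .curation import CurationConfig, curate_scaffolds, summaries_to_frame, verdicts_to_frame
from .domain_profile import (
    DomainSpans,
    TruncationThresholds,
    call_truncation,
    calls_to_frame,
    column_coverage,
    plot_coverage,
)
from .enrichment import EnrichmentConfig, plot_volcano, results_to_frame, test_all_genes
from .errors import SporeAmgError
from .io_ingest import (
    annotations_to_frame,
    build_presence_matrix,
    load_default_catalog,
    read_annotations,
    read_catalog,
    read_hosts,
    read_phages,
)
from .synthetic_data import (
    GeneSpec,
    PopulationSpec,
    RegulatorSeqSpec,
    ScaffoldSpec,
    generate_population,
    generate_regulator_alignment,
    generate_scaffold,
)

logger = logging.getLogger("sporeamg.pipeline")


@dataclass(frozen=True)
class PlantedGene:
    """One deliberately carried gene of the demo population: its carriage
    model plus whether its scaffolds should look genuinely viral."""

    ko_id: str
    p_carry_spore_host: float
    p_carry_other: float
    viral_context: bool = True


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results/run"
    n_phages: int = 800
    frac_spore_host: float = 0.3
    planted_genes: list[PlantedGene] = field(default_factory=list)
    n_null_genes: int = 30
    null_carriage: float = 0.05
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    n_scaffolds_per_gene: int = 8
    viral_n_genes: int = 24
    bacterial_n_genes: int = 20
    alignment: RegulatorSeqSpec = field(default_factory=RegulatorSeqSpec)
    truncation: TruncationThresholds = field(default_factory=TruncationThresholds)
    require_likely_viral: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None, outdir: Optional[str] = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pop = raw.get("population", {})
        planted = [
            PlantedGene(
                ko_id=g["ko_id"],
                p_carry_spore_host=float(g["p_carry_spore_host"]),
                p_carry_other=float(g["p_carry_other"]),
                viral_context=bool(g.get("viral_context", True)),
            )
            for g in pop.get("planted_genes", [])
        ]
        enr = raw.get("enrichment", {})
        cur = raw.get("curation", {})
        aln = raw.get("alignment", {})
        trunc = raw.get("truncation", {})
        cfg = cls(
            seed=int(raw.get("seed", 1)),
            outdir=str(raw.get("outdir", "results/run")),
            n_phages=int(pop.get("n_phages", 800)),
            frac_spore_host=float(pop.get("frac_spore_host", 0.3)),
            planted_genes=planted,
            n_null_genes=int(pop.get("n_null_genes", 30)),
            null_carriage=float(pop.get("null_carriage", 0.05)),
            enrichment=EnrichmentConfig(
                alpha_adj=float(enr.get("alpha_adj", 1e-6)),
                min_n=int(enr.get("min_n", 30)),
                adjust_method=str(enr.get("adjust_method", "BH")),
            ),
            curation=CurationConfig(
                window=int(cur.get("window", 10)),
                flank_reach=int(cur.get("flank_reach", 3)),
                max_nonviral_density=float(cur.get("max_nonviral_density", 0.5)),
                max_strand_switch=float(cur.get("max_strand_switch", 0.4)),
                edge_margin=int(cur.get("edge_margin", 0)),
                possible_viral_max=int(cur.get("possible_viral_max", 5)),
            ),
            n_scaffolds_per_gene=int(cur.get("n_scaffolds_per_gene", 8)),
            viral_n_genes=int(cur.get("viral_n_genes", 24)),
            bacterial_n_genes=int(cur.get("bacterial_n_genes", 20)),
            alignment=RegulatorSeqSpec(
                n_full_length=int(aln.get("n_full_length", 57)),
                n_effector_only=int(aln.get("n_effector_only", 29)),
                receiver_span=tuple(aln.get("receiver_span", (6, 125))),
                effector_span=tuple(aln.get("effector_span", (146, 255))),
                indel_rate=float(aln.get("indel_rate", 0.02)),
                seed=0,  # re-seeded from the run seed below
            ),
            truncation=TruncationThresholds(
                present=float(trunc.get("present", 0.5)),
                absent=float(trunc.get("absent", 0.1)),
            ),
            require_likely_viral=bool(raw.get("require_likely_viral", False)),
            log_level=str(raw.get("log_level", "INFO")),
        )
        if seed is not None:
            cfg.seed = int(seed)
        if outdir is not None:
            cfg.outdir = str(outdir)
        return cfg

    def gene_specs(self) -> list[GeneSpec]:
        specs = [
            GeneSpec(
                ko_id=g.ko_id,
                p_carry_spore_host=g.p_carry_spore_host,
                p_carry_other=g.p_carry_other,
                is_sporulation=True,
            )
            for g in self.planted_genes
        ]
        specs += [
            GeneSpec(
                ko_id=f"KN{i + 1:04d}",
                p_carry_spore_host=self.null_carriage,
                p_carry_other=self.null_carriage,
                is_sporulation=False,
            )
            for i in range(self.n_null_genes)
        ]
        return specs

    def echo(self) -> dict:
        out = {
            "seed": self.seed,
            "n_phages": self.n_phages,
            "frac_spore_host": self.frac_spore_host,
            "planted_genes": [asdict(g) for g in self.planted_genes],
            "n_null_genes": self.n_null_genes,
            "null_carriage": self.null_carriage,
            "enrichment": asdict(self.enrichment),
            "curation": {
                k: v
                for k, v in asdict(self.curation).items()
                if k not in ("hallmark_keywords", "hypothetical_keywords")
            },
            "n_scaffolds_per_gene": self.n_scaffolds_per_gene,
            "alignment": asdict(self.alignment),
            "truncation": asdict(self.truncation),
            "require_likely_viral": self.require_likely_viral,
        }
        return out


def default_config_path() -> Path:
    from importlib import resources

    ref = resources.files("sporeamg.data").joinpath("demo_config.yaml")
    with resources.as_file(ref) as path:
        return Path(path)


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 9973 + offset) % (2**31 - 1)


def _catalog_for(config: RunConfig):
    """Catalog entries for every simulated KO; planted genes inherit names
    from the packaged sporulation catalog where the KO matches."""
    from .io_ingest import GeneCatalogEntry

    known = {e.ko_id: e for e in load_default_catalog()}
    entries = []
    for spec in config.gene_specs():
        base = known.get(spec.ko_id)
        entries.append(
            GeneCatalogEntry(
                ko_id=spec.ko_id,
                locus=base.locus if base else "synthetic",
                gene_name=base.gene_name if base else spec.ko_id,
                reg_type=base.reg_type if base else "U",
                function=base.function if base else "synthetic null gene",
                is_sporulation=spec.is_sporulation,
            )
        )
    return entries


def _catalog_to_frame(entries) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "ko_id": [e.ko_id for e in entries],
            "locus": [e.locus for e in entries],
            "gene_name": [e.gene_name for e in entries],
            "reg_type": [e.reg_type for e in entries],
            "function": [e.function for e in entries],
            "is_sporulation": [e.is_sporulation for e in entries],
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as
    ``report.json``).  A stage failure aborts with the failing stage named;
    outputs written so far are retained and MANIFEST marks the run
    incomplete."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sporeamg")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: list[str] = []
    stage = "startup"

    def _wrote(name: str) -> Path:
        manifest.append(name)
        return outdir / name

    try:
        report: dict = {"version": __version__, "config": config.echo(), "stages": {}}
        # ------------------------------------------------------------ simulate
        stage = "simulate"
        logger.info("stage %s", stage)
        pop_spec = PopulationSpec(
            n_phages=config.n_phages,
            frac_spore_host=config.frac_spore_host,
            gene_specs=tuple(config.gene_specs()),
            seed=_sub_seed(config.seed, 1),
        )
        tables = generate_population(pop_spec)
        tables.hosts.to_csv(_wrote("hosts.tsv"), sep="\t", index=False)
        tables.phages.to_csv(_wrote("phages.tsv"), sep="\t", index=False)
        tables.annotations.to_csv(_wrote("annotations.tsv"), sep="\t", index=False)
        tables.truth.to_csv(_wrote("truth.tsv"), sep="\t", index=False)

        catalog_entries = _catalog_for(config)
        _catalog_to_frame(catalog_entries).to_csv(
            _wrote("catalog.tsv"), sep="\t", index=False
        )

        scaffold_maps = []
        scaffold_truth = {}
        idx = 0
        for gene in config.planted_genes:
            kind = "viral" if gene.viral_context else "bacterial"
            for _ in range(config.n_scaffolds_per_gene):
                idx += 1
                sspec = ScaffoldSpec(
                    kind=kind,
                    n_genes=config.viral_n_genes
                    if kind == "viral"
                    else config.bacterial_n_genes,
                    focal_ko=gene.ko_id,
                    seed=_sub_seed(config.seed, 1000 + idx),
                    scaffold_id=f"{gene.ko_id}_scaf{idx:04d}",
                )
                smap = generate_scaffold(sspec)
                scaffold_maps.append(smap)
                scaffold_truth[smap.scaffold_id] = kind
        all_scaffold_genes = [g for m in scaffold_maps for g in m.genes]
        annotations_to_frame(all_scaffold_genes).to_csv(
            _wrote("scaffold_annotations.tsv"), sep="\t", index=False
        )

        aln_spec = RegulatorSeqSpec(
            n_full_length=config.alignment.n_full_length,
            n_effector_only=config.alignment.n_effector_only,
            receiver_span=config.alignment.receiver_span,
            effector_span=config.alignment.effector_span,
            indel_rate=config.alignment.indel_rate,
            seed=_sub_seed(config.seed, 2),
        )
        aln = generate_regulator_alignment(aln_spec)
        aln.to_fasta(_wrote("alignment.afa"), _wrote("labels.tsv"))
        report["stages"]["simulate"] = {
            "n_phages": int(len(tables.phages)),
            "n_annotation_rows": int(len(tables.annotations)),
            "n_genes_simulated": int(len(tables.truth)),
            "n_scaffolds": len(scaffold_maps),
            "n_aligned_sequences": len(aln.ids),
        }

        # -------------------------------------------------------------- ingest
        stage = "ingest"
        logger.info("stage %s", stage)
        annotations = read_annotations(outdir / "annotations.tsv")
        phages = read_phages(outdir / "phages.tsv")
        hosts = read_hosts(outdir / "hosts.tsv")
        catalog = read_catalog(outdir / "catalog.tsv")
        matrix = build_presence_matrix(annotations, phages, hosts, catalog)
        report["stages"]["ingest"] = {
            "N": matrix.N,
            "K": matrix.K,
            "n_catalog_kos": len(matrix.genes),
            "n_excluded_no_host": matrix.n_excluded_no_host,
        }

        # -------------------------------------------------------------- enrich
        stage = "enrich"
        logger.info("stage %s", stage)
        results = test_all_genes(matrix, config.enrichment)
        results_to_frame(results, catalog).to_csv(
            _wrote("enrichment.tsv"), sep="\t", index=False
        )
        plot_volcano(results, _wrote("volcano.svg"), config.enrichment)
        enriched = [r.ko_id for r in results if r.enriched]
        report["stages"]["enrich"] = {
            "n_tested": len(results),
            "enriched_genes": sorted(enriched),
        }

        # -------------------------------------------------------------- curate
        stage = "curate"
        logger.info("stage %s", stage)
        inspect = [m for m in scaffold_maps if m.focal_gene.ko_id in enriched]
        verdicts, summaries = curate_scaffolds(inspect, config.curation)
        verdicts_to_frame(verdicts).to_csv(_wrote("verdicts.tsv"), sep="\t", index=False)
        summaries_to_frame(summaries).to_csv(
            _wrote("gene_summary.tsv"), sep="\t", index=False
        )
        category = {s.ko_id: s.category for s in summaries}
        report["stages"]["curate"] = {
            "n_scaffolds_inspected": len(verdicts),
            "categories": dict(sorted(category.items())),
        }

        # ------------------------------------------------------------- profile
        stage = "profile"
        logger.info("stage %s", stage)
        spans = DomainSpans(
            receiver=config.alignment.receiver_span,
            effector=config.alignment.effector_span,
        )
        coverage = column_coverage(aln)
        coverage.round(4).to_csv(_wrote("coverage.tsv"), sep="\t")
        calls = call_truncation(aln, spans, config.truncation)
        calls_to_frame(calls).to_csv(
            _wrote("truncation_calls.tsv"), sep="\t", index=False
        )
        plot_coverage(coverage, spans, _wrote("coverage.svg"))
        tallies: dict[str, int] = {}
        for c in calls:
            tallies[c.call] = tallies.get(c.call, 0) + 1
        report["stages"]["profile"] = {"truncation_tallies": dict(sorted(tallies.items()))}

        # ---------------------------------------------------------- candidates
        stage = "candidates"
        logger.info("stage %s", stage)
        keep = (
            {"likely viral"}
            if config.require_likely_viral
            else {"likely viral", "possible viral"}
        )
        candidates = sorted(
            ko for ko in enriched if category.get(ko, "unlikely viral") in keep
        )
        import pandas as pd

        pd.DataFrame(
            {
                "ko_id": candidates,
                "category": [category[k] for k in candidates],
                "flagged_possible": [category[k] == "possible viral" for k in candidates],
            }
        ).to_csv(_wrote("candidates.tsv"), sep="\t", index=False)
        report["stages"]["candidates"] = {"candidate_genes": candidates}
        report["candidate_genes"] = candidates

        report["planted_truth"] = {
            "enriched": sorted(
                g.ko_id
                for g in config.planted_genes
                if g.p_carry_spore_host > g.p_carry_other
            ),
            "enriched_and_viral_context": sorted(
                g.ko_id
                for g in config.planted_genes
                if g.p_carry_spore_host > g.p_carry_other and g.viral_context
            ),
        }

        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        manifest.append("report.json")
        (outdir / "MANIFEST").write_text(
            "status\tcomplete\n" + "".join(f"file\t{m}\n" for m in sorted(manifest))
        )
        return report
    except Exception as exc:
        (outdir / "MANIFEST").write_text(
            f"status\tincomplete\nfailed_stage\t{stage}\n"
            + "".join(f"file\t{m}\n" for m in sorted(manifest))
        )
        logger.error("stage %s failed: %s", stage, exc)
        if isinstance(exc, SporeAmgError):
            raise
        raise SporeAmgError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
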