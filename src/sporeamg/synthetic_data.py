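"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the three kinds of evidence the pipeline consumes:

* :func:`generate_population` — a phage population with one predicted host
  per phage, a fixed fraction of spore-forming hosts, and per-gene carriage
  probabilities that differ (or not) between spore-host and other phages.
  This is the substrate of the enrichment test: the ground-truth table says
  which genes were planted as enriched.
* :func:`generate_scaffold` — annotated gene maps of three kinds: a clean
  viral scaffold (focal gene nested between hallmark viral genes amid
  hypothetical proteins, few strand switches), a bacterial fragment (dense
  housekeeping annotation, frequent strand switches), or a chimera whose
  bacterial block carries the focal gene.  These exercise the curation
  rules.
* :func:`generate_regulator_alignment` — a pre-aligned protein set of
  full-length two-domain regulators ("bacteria") and effector-only
  truncations ("virome"), for the coverage/truncation stage.

All randomness flows from the spec's seed through one
``numpy.random.Generator``; identical specs give byte-identical outputs.
Strand switches are placed at evenly spaced adjacent pairs so that the
switch fraction in any local window tracks the requested global rate — this
is what makes the scaffold kinds separable by the curation thresholds by
construction rather than merely in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import ScaffoldMap
from .domain_profile import GroupedAlignment
from .errors import ValidationError
from .io_ingest import GeneAnnotation

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

SPORE_FORMER_TAXA = (
    "Bacillus subtilis",
    "Bacillus cereus",
    "Clostridioides difficile",
    "Clostridium butyricum",
    "Paenibacillus polymyxa",
    "Romboutsia ilealis",
)
NON_SPORE_FORMER_TAXA = (
    "Escherichia coli",
    "Bacteroides fragilis",
    "Lactobacillus gasseri",
    "Akkermansia muciniphila",
    "Prevotella copri",
    "Faecalibacterium prausnitzii",
)

#: Hallmark-viral phrases; each contains one of the curation keyword terms.
HALLMARK_PHRASES = (
    "major capsid protein",
    "phage terminase large subunit",
    "tail fiber protein",
    "baseplate wedge subunit",
    "portal protein, phage associated",
    "virion structural protein",
    "head-tail connector protein",
    "minor tail protein",
    "phage holin",
    "virus attachment protein",
)

#: Housekeeping phrases classified "other annotation" (no hallmark or
#: hypothetical keywords appear in any of them).
HOUSEKEEPING_PHRASES = (
    "DNA gyrase subunit A",
    "30S ribosomal protein S12",
    "ATP synthase subunit beta",
    "elongation factor Tu",
    "citrate synthase",
    "DNA polymerase III subunit alpha",
    "preprotein translocase subunit SecY",
    "NADH-quinone oxidoreductase subunit B",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "aspartate aminotransferase",
    "peptide chain release factor 1",
    "UDP-N-acetylglucosamine 1-carboxyvinyltransferase",
)

HYPOTHETICAL_PHRASES = (
    "hypothetical protein",
    "uncharacterized protein",
    "protein of unknown function",
)

DEFAULT_GENE_LENGTH = 900  # bp; coordinates only need to order genes
DEFAULT_SPACER = 100  # bp between consecutive genes


def _check_fraction(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name}: {value} not in [0, 1]")


@dataclass(frozen=True)
class GeneSpec:
    """Carriage model of one KO: independent Bernoulli presence per phage,
    with different probabilities for spore-host and other phages."""

    ko_id: str
    p_carry_spore_host: float
    p_carry_other: float
    is_sporulation: bool = True

    def __post_init__(self) -> None:
        _check_fraction(self.p_carry_spore_host, "p_carry_spore_host")
        _check_fraction(self.p_carry_other, "p_carry_other")

    @property
    def label(self) -> str:
        """Ground truth: "enriched" iff spore-host carriage is strictly higher."""
        return "enriched" if self.p_carry_spore_host > self.p_carry_other else "null"


@dataclass(frozen=True)
class PopulationSpec:
    n_phages: int
    frac_spore_host: float
    gene_specs: tuple[GeneSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phages < 1:
            raise ValidationError(f"n_phages: {self.n_phages} must be >= 1")
        _check_fraction(self.frac_spore_host, "frac_spore_host")
        object.__setattr__(self, "gene_specs", tuple(self.gene_specs))


@dataclass
class PopulationTables:
    """The four tables of one simulated population."""

    hosts: pd.DataFrame
    phages: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.hosts.to_csv(outdir / "hosts.tsv", sep="\t", index=False)
        self.phages.to_csv(outdir / "phages.tsv", sep="\t", index=False)
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def generate_population(spec: PopulationSpec) -> PopulationTables:
    """Simulate hosts, phages, gene annotations and the ground-truth table.

    Exactly ``round(frac_spore_host * n_phages)`` phages get a spore-forming
    host (the fraction is rounding-exact, not sampled).  Presence of each
    gene in each phage is an independent Bernoulli draw at the carriage
    probability matching the phage's host trait.
    """
    rng = np.random.default_rng(spec.seed)

    host_ids, taxa, traits = [], [], []
    for i, taxon in enumerate(SPORE_FORMER_TAXA):
        host_ids.append(f"HS{i + 1:02d}")
        taxa.append(taxon)
        traits.append(True)
    for i, taxon in enumerate(NON_SPORE_FORMER_TAXA):
        host_ids.append(f"HN{i + 1:02d}")
        taxa.append(taxon)
        traits.append(False)
    hosts = pd.DataFrame(
        {"host_id": host_ids, "taxon": taxa, "is_spore_former": traits}
    )

    n_spore = round(spec.frac_spore_host * spec.n_phages)
    spore_hosts = hosts.host_id[hosts.is_spore_former].to_numpy()
    other_hosts = hosts.host_id[~hosts.is_spore_former].to_numpy()
    phage_ids = [f"P{j + 1:05d}" for j in range(spec.n_phages)]
    is_spore = np.zeros(spec.n_phages, dtype=bool)
    is_spore[:n_spore] = True
    rng.shuffle(is_spore)
    assigned = [
        rng.choice(spore_hosts) if s else rng.choice(other_hosts) for s in is_spore
    ]
    phages = pd.DataFrame(
        {"phage_id": phage_ids, "host_id": assigned, "source": "synthetic"}
    )

    # presence draws: one Bernoulli matrix column block per gene
    present: dict[str, np.ndarray] = {}
    for gene in spec.gene_specs:
        p = np.where(is_spore, gene.p_carry_spore_host, gene.p_carry_other)
        present[gene.ko_id] = rng.random(spec.n_phages) < p

    rows: list[dict] = []
    for j, pid in enumerate(phage_ids):
        scaffold = f"{pid}_scaf1"
        idx = 0
        for gene in spec.gene_specs:
            if not present[gene.ko_id][j]:
                continue
            start = 1 + idx * (DEFAULT_GENE_LENGTH + DEFAULT_SPACER)
            rows.append(
                {
                    "gene_id": f"{scaffold}_g{idx + 1:03d}",
                    "scaffold_id": scaffold,
                    "phage_id": pid,
                    "start": start,
                    "end": start + DEFAULT_GENE_LENGTH - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "ko_id": gene.ko_id,
                    "description": f"{gene.ko_id} family protein",
                }
            )
            idx += 1
    annotations = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "scaffold_id",
            "phage_id",
            "start",
            "end",
            "strand",
            "ko_id",
            "description",
        ],
    )

    truth = pd.DataFrame(
        {
            "ko_id": [g.ko_id for g in spec.gene_specs],
            "label": [g.label for g in spec.gene_specs],
            "p_carry_spore_host": [g.p_carry_spore_host for g in spec.gene_specs],
            "p_carry_other": [g.p_carry_other for g in spec.gene_specs],
            "is_sporulation": [g.is_sporulation for g in spec.gene_specs],
        }
    )
    return PopulationTables(hosts=hosts, phages=phages, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# scaffold generation


@dataclass(frozen=True)
class ScaffoldSpec:
    """Blueprint of one scaffold gene map.

    ``strand_switch_rate`` is an upper bound on the adjacent-pair strand
    switch fraction for viral scaffolds and a lower bound for bacterial
    ones; ``hypothetical_fraction`` is the fraction of non-focal, non-flank
    genes left unannotated.  ``None`` selects a kind-appropriate default
    (viral: rate 0.1, hypothetical 0.8; bacterial: rate 0.5, hypothetical
    0.2; chimeric blocks use the respective kind defaults).
    """

    kind: str  # "viral" | "bacterial" | "chimeric"
    n_genes: int = 20
    focal_ko: str = "K07699"
    focal_position: str = "interior"  # "interior" | "edge"
    hypothetical_fraction: Optional[float] = None
    strand_switch_rate: Optional[float] = None
    seed: int = 0
    scaffold_id: Optional[str] = None

    _MIN_GENES = {"viral": 7, "bacterial": 3, "chimeric": 12}

    def __post_init__(self) -> None:
        if self.kind not in self._MIN_GENES:
            raise ValidationError(f"kind: {self.kind!r} not viral/bacterial/chimeric")
        if self.focal_position not in {"interior", "edge"}:
            raise ValidationError(
                f"focal_position: {self.focal_position!r} not interior/edge"
            )
        if self.n_genes < self._MIN_GENES[self.kind]:
            raise ValidationError(
                f"n_genes: {self.n_genes} too small for kind={self.kind!r} "
                f"(need >= {self._MIN_GENES[self.kind]} to honor flanking "
                "constraints)"
            )
        if self.hypothetical_fraction is not None:
            _check_fraction(self.hypothetical_fraction, "hypothetical_fraction")
        if self.strand_switch_rate is not None:
            _check_fraction(self.strand_switch_rate, "strand_switch_rate")

    @property
    def resolved_switch_rate(self) -> float:
        if self.strand_switch_rate is not None:
            return self.strand_switch_rate
        return 0.1 if self.kind == "viral" else 0.5

    @property
    def resolved_hypothetical_fraction(self) -> float:
        if self.hypothetical_fraction is not None:
            return self.hypothetical_fraction
        return 0.8 if self.kind == "viral" else 0.2


def _evenly_spaced_switches(n_pairs: int, n_switches: int, rng) -> np.ndarray:
    """Pick ``n_switches`` distinct pair indices spread evenly over the
    scaffold (random phase), so local windows see the global switch rate."""
    if n_switches <= 0 or n_pairs <= 0:
        return np.zeros(0, dtype=int)
    n_switches = min(n_switches, n_pairs)
    phase = rng.random()
    idx = np.floor((np.arange(n_switches) + phase) * n_pairs / n_switches)
    return np.unique(idx.astype(int).clip(0, n_pairs - 1))


def _strands(n_genes: int, n_switches: int, rng) -> list[str]:
    switch_at = set(_evenly_spaced_switches(n_genes - 1, n_switches, rng).tolist())
    strand = "+" if rng.random() < 0.5 else "-"
    out = [strand]
    for pair in range(n_genes - 1):
        if pair in switch_at:
            strand = "+" if strand == "-" else "-"
        out.append(strand)
    return out


def _viral_descriptions(
    n_genes: int,
    focal: int,
    hyp_frac: float,
    rng,
    flank_reach: int = 3,
) -> list[str]:
    """Viral-kind descriptions: hallmark genes within ``flank_reach`` of the
    focal gene on each existing side; the rest mostly hypothetical."""
    desc: list[Optional[str]] = [None] * n_genes
    for side in (-1, +1):
        candidates = [
            focal + side * off
            for off in range(1, flank_reach + 1)
            if 0 <= focal + side * off < n_genes
        ]
        if candidates:
            desc[int(rng.choice(candidates))] = str(rng.choice(HALLMARK_PHRASES))
    for i in range(n_genes):
        if i == focal or desc[i] is not None:
            continue
        u = rng.random()
        if u < hyp_frac:
            desc[i] = str(rng.choice(HYPOTHETICAL_PHRASES))
        elif u < hyp_frac + (1 - hyp_frac) * 0.75:
            desc[i] = str(rng.choice(HALLMARK_PHRASES))
        else:
            desc[i] = str(rng.choice(HOUSEKEEPING_PHRASES))
    return desc  # type: ignore[return-value]


def _bacterial_descriptions(n_genes: int, focal: int, hyp_frac: float, rng) -> list[str]:
    desc = []
    for i in range(n_genes):
        if i == focal:
            desc.append(None)
        elif rng.random() < hyp_frac:
            desc.append(str(rng.choice(HYPOTHETICAL_PHRASES)))
        else:
            desc.append(str(rng.choice(HOUSEKEEPING_PHRASES)))
    return desc


FOCAL_DESCRIPTION = "stage 0 sporulation protein A"


def _assemble(
    scaffold_id: str,
    descriptions: Sequence[Optional[str]],
    strands: Sequence[str],
    focal: int,
    focal_ko: str,
) -> ScaffoldMap:
    genes = []
    for i, (desc, strand) in enumerate(zip(descriptions, strands)):
        start = 1 + i * (DEFAULT_GENE_LENGTH + DEFAULT_SPACER)
        genes.append(
            GeneAnnotation(
                gene_id=f"{scaffold_id}_g{i + 1:03d}",
                scaffold_id=scaffold_id,
                start=start,
                end=start + DEFAULT_GENE_LENGTH - 1,
                strand=strand,
                ko_id=focal_ko if i == focal else None,
                description=FOCAL_DESCRIPTION if i == focal else (desc or ""),
            )
        )
    return ScaffoldMap(
        scaffold_id=scaffold_id,
        genes=genes,
        focal_gene_id=f"{scaffold_id}_g{focal + 1:03d}",
    )


def generate_scaffold(spec: ScaffoldSpec) -> ScaffoldMap:
    """Generate one scaffold gene map of the requested kind.

    viral: focal gene interior (unless ``focal_position="edge"``) with a
    hallmark-viral gene within 3 positions on each existing side, remaining
    genes mostly hypothetical, strand-switch fraction <= the resolved rate.
    bacterial: >= 60% housekeeping annotations, no hallmark genes,
    strand-switch fraction >= the resolved rate.  chimeric: a bacterial
    block carrying the focal gene followed by a viral block.
    """
    rng = np.random.default_rng(spec.seed)
    sid = spec.scaffold_id or f"{spec.kind}_scaf_{spec.seed:06d}"
    n = spec.n_genes
    rate = spec.resolved_switch_rate
    hyp = spec.resolved_hypothetical_fraction

    if spec.kind == "viral":
        if spec.focal_position == "edge":
            focal = 0 if rng.random() < 0.5 else n - 1
        else:
            focal = int(rng.integers(3, n - 3))
        desc = _viral_descriptions(n, focal, hyp, rng)
        strands = _strands(n, int(np.floor(rate * (n - 1))), rng)
        return _assemble(sid, desc, strands, focal, spec.focal_ko)

    if spec.kind == "bacterial":
        if spec.focal_position == "edge":
            focal = 0 if rng.random() < 0.5 else n - 1
        else:
            lo, hi = max(1, n // 3), max(2, n - max(1, n // 3))
            focal = int(rng.integers(lo, hi))
        desc = _bacterial_descriptions(n, focal, hyp, rng)
        strands = _strands(n, int(np.ceil(rate * (n - 1))), rng)
        return _assemble(sid, desc, strands, focal, spec.focal_ko)

    # chimeric: bacterial block (with focal at its center) + viral block
    n_bac = max(int(np.ceil(0.7 * n)), 8)
    n_vir = n - n_bac
    focal = n_bac // 2
    desc = _bacterial_descriptions(n_bac, focal, 0.2, rng)
    desc += [
        str(rng.choice(HALLMARK_PHRASES))
        if rng.random() < 0.3
        else str(rng.choice(HYPOTHETICAL_PHRASES))
        for _ in range(n_vir)
    ]
    strands = _strands(n_bac, int(np.ceil(0.5 * (n_bac - 1))), rng)
    strands += _strands(n_vir, int(np.floor(0.1 * max(n_vir - 1, 0))), rng)
    return _assemble(sid, desc, strands, focal, spec.focal_ko)


def scaffold_truth_verdict(spec: ScaffoldSpec) -> str:
    """The curation verdict a correct rule engine should reach."""
    if spec.focal_position == "edge":
        return "false"
    return "true" if spec.kind == "viral" else "false"


# ---------------------------------------------------------------------------
# regulator alignment generation


@dataclass(frozen=True)
class RegulatorSeqSpec:
    """Design of the synthetic two-domain regulator alignment.

    Default spans sketch a spo0A-like architecture: a ~120-column receiver
    domain, a 20-column linker, and a ~110-column DNA-binding effector
    domain.  ``indel_rate`` flips residues to gaps per column per sequence,
    but never creates residues inside the receiver span of effector-only
    sequences, so truncation ground truth survives the noise.
    """

    n_full_length: int = 57
    n_effector_only: int = 29
    receiver_span: tuple[int, int] = (6, 125)
    effector_span: tuple[int, int] = (146, 255)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_full_length < 0 or self.n_effector_only < 0:
            raise ValidationError("sequence counts must be >= 0")
        if self.n_full_length + self.n_effector_only == 0:
            raise ValidationError("at least one sequence is required")
        _check_fraction(self.indel_rate, "indel_rate")
        r, e = self.receiver_span, self.effector_span
        for name, (lo, hi) in (("receiver_span", r), ("effector_span", e)):
            if not 1 <= lo <= hi:
                raise ValidationError(f"{name}: {lo}-{hi} is not a valid interval")
        if r[1] >= e[0]:
            raise ValidationError(
                f"receiver_span {r} must end before effector_span {e} begins"
            )

    @property
    def alignment_length(self) -> int:
        return self.effector_span[1] + 5


def generate_regulator_alignment(spec: RegulatorSeqSpec) -> GroupedAlignment:
    """Generate the aligned FASTA content with source labels.

    Full-length sequences ("bacteria") carry residues over every column;
    effector-only sequences ("virome") carry residues only across the
    effector span.  Gap noise is then applied at ``indel_rate`` (residue ->
    gap flips only, and never within the receiver span of effector-only
    sequences, which is all-gap by construction).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.alignment_length
    r_lo, r_hi = spec.receiver_span
    e_lo, e_hi = spec.effector_span

    ids, seqs, labels = [], [], {}

    def _noise(chars: np.ndarray, protect: Optional[slice]) -> None:
        if spec.indel_rate == 0:
            return
        flips = rng.random(L) < spec.indel_rate
        if protect is not None:
            flips[protect] = False
        chars[flips & (chars != "-")] = "-"

    for i in range(spec.n_full_length):
        chars = rng.choice(AMINO_ACIDS, size=L)
        _noise(chars, protect=None)
        sid = f"bact_{i + 1:03d}"
        ids.append(sid)
        seqs.append("".join(chars))
        labels[sid] = "bacteria"

    for i in range(spec.n_effector_only):
        chars = np.full(L, "-", dtype="<U1")
        chars[e_lo - 1 : e_hi] = rng.choice(AMINO_ACIDS, size=e_hi - e_lo + 1)
        _noise(chars, protect=slice(r_lo - 1, r_hi))
        sid = f"vir_{i + 1:03d}"
        ids.append(sid)
        seqs.append("".join(chars))
        labels[sid] = "virome"

    return GroupedAlignment(ids=ids, seqs=seqs, labels=labels)
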