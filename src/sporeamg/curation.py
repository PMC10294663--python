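"""Automated viral-origin curation of scaffolds carrying a focal gene.

Sporulation-gene hits on metagenome-assembled viral scaffolds can come from
bacterial contamination rather than a phage genome.  This module codifies
the manual-inspection logic used to separate the two into a deterministic
rule engine over per-scaffold features:

* ``is_edge`` — the focal gene sits at a scaffold end, where chimeric
  assembly breakpoints concentrate; an edge hit is rejected outright.
* ``nonviral_density`` and ``strand_switch_frac`` — bacterial genome
  fragments are densely annotated with non-viral functions and flip gene
  direction often, whereas phage gene blocks are operon-like (few strand
  switches) and dominated by hypothetical proteins.  Rejection requires BOTH
  signals to be high; either alone yields "maybe".
* ``hallmark_flanked`` — a focal gene nested between hallmark viral genes
  (capsid, terminase, tail, ...) on both sides is accepted as viral.

Per-gene verdict tallies are then binned into "likely viral" (>= 5 scaffolds
called true), "possible viral" (1-4), or "unlikely viral" (none).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io_ingest import GeneAnnotation


class GeneClass(str, enum.Enum):
    HALLMARK_VIRAL = "hallmark_viral"
    HYPOTHETICAL = "hypothetical"
    OTHER_ANNOTATION = "other_annotation"


#: Annotation substrings that mark a gene as hallmark-viral.
DEFAULT_HALLMARK_KEYWORDS = (
    "virion",
    "capsid",
    "tail",
    "terminase",
    "baseplate",
    "phage",
    "virus",
    "reverse transcriptase",
    "head",
)

DEFAULT_HYPOTHETICAL_KEYWORDS = ("hypothetical", "uncharacterized", "unknown function")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the rule engine.

    All cutoffs operationalize qualitative inspection criteria and are
    deliberately configurable; they are echoed into every output table.
    """

    hallmark_keywords: tuple[str, ...] = DEFAULT_HALLMARK_KEYWORDS
    hypothetical_keywords: tuple[str, ...] = DEFAULT_HYPOTHETICAL_KEYWORDS
    window: int = 10  # genes on each side of the focal gene
    flank_reach: int = 3  # hallmark must occur within this many genes, each side
    max_nonviral_density: float = 0.5
    max_strand_switch: float = 0.4
    edge_margin: int = 0  # 0 = only the first/last gene counts as edge
    possible_viral_max: int = 5  # n_true below this (and >=1) -> "possible viral"

    def __post_init__(self) -> None:
        for name in ("max_nonviral_density", "max_strand_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: {v} not in [0, 1]")
        if not self.window >= self.flank_reach >= 1:
            raise ValidationError(
                f"window ({self.window}) must be >= flank_reach "
                f"({self.flank_reach}) >= 1"
            )
        object.__setattr__(
            self, "hallmark_keywords", tuple(k.lower() for k in self.hallmark_keywords)
        )
        object.__setattr__(
            self,
            "hypothetical_keywords",
            tuple(k.lower() for k in self.hypothetical_keywords),
        )


@dataclass
class ScaffoldMap:
    """Ordered gene annotations along one scaffold plus the focal gene."""

    scaffold_id: str
    genes: list[GeneAnnotation]
    focal_gene_id: str

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if self.focal_gene_id not in ids:
            raise ValidationError(
                f"focal_gene_id {self.focal_gene_id!r} not on scaffold "
                f"{self.scaffold_id}"
            )
        prev_end = 0
        for g in self.genes:
            if g.start <= prev_end:
                raise ValidationError(
                    f"scaffold {self.scaffold_id}: overlapping/unsorted gene "
                    f"intervals at {g.gene_id}"
                )
            prev_end = g.end

    @property
    def focal_index(self) -> int:
        return next(
            i for i, g in enumerate(self.genes) if g.gene_id == self.focal_gene_id
        )

    @property
    def focal_gene(self) -> GeneAnnotation:
        return self.genes[self.focal_index]


@dataclass(frozen=True)
class ScaffoldFeatures:
    is_edge: bool
    strand_switch_frac: float
    nonviral_density: float
    hallmark_flanked: bool
    hypothetical_frac: float


@dataclass(frozen=True)
class ScaffoldVerdict:
    scaffold_id: str
    ko_id: str
    verdict: str  # "true" | "false" | "maybe"
    features: ScaffoldFeatures
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class GeneCurationSummary:
    ko_id: str
    n_scaffolds_detected: int
    n_inspected: int
    n_true: int
    n_false: int
    n_maybe: int
    category: str  # "likely viral" | "possible viral" | "unlikely viral"


def classify_gene(description: str, config: CurationConfig | None = None) -> GeneClass:
    """Classify a free-text annotation into the three map colors.

    Hallmark keywords win over hypothetical ones; an empty description is
    hypothetical; anything else is "other annotation".  Matching is
    case-insensitive substring over the full description, so concatenated
    KEGG+Pfam text is handled.
    """
    config = config or CurationConfig()
    text = description.lower()
    if any(kw in text for kw in config.hallmark_keywords):
        return GeneClass.HALLMARK_VIRAL
    if not text.strip() or any(kw in text for kw in config.hypothetical_keywords):
        return GeneClass.HYPOTHETICAL
    return GeneClass.OTHER_ANNOTATION


def extract_features(
    smap: ScaffoldMap, config: CurationConfig | None = None
) -> ScaffoldFeatures:
    """Compute the rule-engine features for one scaffold.

    Density and hypothetical fractions are taken over the genes within
    ``config.window`` positions of the focal gene (focal excluded); the
    strand-switch fraction is over adjacent pairs within that same window
    (focal included, since its own strand is informative context).
    """
    config = config or CurationConfig()
    n = len(smap.genes)
    f = smap.focal_index

    is_edge = f <= config.edge_margin or f >= n - 1 - config.edge_margin

    lo = max(0, f - config.window)
    hi = min(n, f + config.window + 1)
    window_genes = smap.genes[lo:hi]

    pairs = len(window_genes) - 1
    switches = sum(
        1
        for a, b in zip(window_genes, window_genes[1:])
        if a.strand != b.strand
    )
    strand_switch_frac = switches / pairs if pairs else 0.0

    classes = [
        classify_gene(g.description, config)
        for g in window_genes
        if g.gene_id != smap.focal_gene_id
    ]
    n_ctx = len(classes)
    nonviral_density = (
        sum(c is GeneClass.OTHER_ANNOTATION for c in classes) / n_ctx if n_ctx else 0.0
    )
    hypothetical_frac = (
        sum(c is GeneClass.HYPOTHETICAL for c in classes) / n_ctx if n_ctx else 0.0
    )

    def _has_hallmark(indices: Iterable[int]) -> bool:
        return any(
            classify_gene(smap.genes[i].description, config)
            is GeneClass.HALLMARK_VIRAL
            for i in indices
        )

    left = range(max(0, f - config.flank_reach), f)
    right = range(f + 1, min(n, f + config.flank_reach + 1))
    hallmark_flanked = _has_hallmark(left) and _has_hallmark(right)

    return ScaffoldFeatures(
        is_edge=is_edge,
        strand_switch_frac=strand_switch_frac,
        nonviral_density=nonviral_density,
        hallmark_flanked=hallmark_flanked,
        hypothetical_frac=hypothetical_frac,
    )


def score_scaffold(
    smap: ScaffoldMap,
    config: CurationConfig | None = None,
    features: ScaffoldFeatures | None = None,
) -> ScaffoldVerdict:
    """Apply the accept/reject rules and return the verdict with fired rules.

    Reject ("false"): focal gene at the scaffold edge, or the window looks
    bacterial (high non-viral density AND high strand-switch frequency).
    Accept ("true"): not rejected, hallmark-flanked, and low non-viral
    density.  Anything else is "maybe".
    """
    config = config or CurationConfig()
    feats = features if features is not None else extract_features(smap, config)

    reasons: list[str] = []
    if feats.is_edge:
        reasons.append("edge_reject")
    bacterial_context = (
        feats.nonviral_density > config.max_nonviral_density
        and feats.strand_switch_frac > config.max_strand_switch
    )
    if bacterial_context:
        reasons.append("bacterial_context_reject")

    if reasons:
        verdict = "false"
    elif feats.hallmark_flanked and feats.nonviral_density <= config.max_nonviral_density:
        verdict = "true"
        reasons.append("hallmark_flanked_accept")
    else:
        verdict = "maybe"
        reasons.append("no_rule_fired")

    focal_ko = smap.focal_gene.ko_id or ""
    return ScaffoldVerdict(
        scaffold_id=smap.scaffold_id,
        ko_id=focal_ko,
        verdict=verdict,
        features=feats,
        reasons=tuple(reasons),
    )


def summarize_gene(
    verdicts: Sequence[ScaffoldVerdict],
    n_scaffolds_detected: int | None = None,
    config: CurationConfig | None = None,
) -> GeneCurationSummary:
    """Tally one gene's scaffold verdicts into a per-gene origin category."""
    config = config or CurationConfig()
    if not verdicts:
        raise ValidationError("summarize_gene: empty verdict list")
    kos = {v.ko_id for v in verdicts}
    if len(kos) != 1:
        raise ValidationError(f"summarize_gene: mixed KO ids {sorted(kos)}")
    n_inspected = len(verdicts)
    if n_scaffolds_detected is None:
        n_scaffolds_detected = n_inspected
    if n_scaffolds_detected < n_inspected:
        raise ValidationError(
            "summarize_gene: n_scaffolds_detected < number of verdicts"
        )
    n_true = sum(v.verdict == "true" for v in verdicts)
    n_false = sum(v.verdict == "false" for v in verdicts)
    n_maybe = n_inspected - n_true - n_false

    if n_true == 0:
        category = "unlikely viral"
    elif n_true < config.possible_viral_max:
        category = "possible viral"
    else:
        category = "likely viral"

    return GeneCurationSummary(
        ko_id=kos.pop(),
        n_scaffolds_detected=n_scaffolds_detected,
        n_inspected=n_inspected,
        n_true=n_true,
        n_false=n_false,
        n_maybe=n_maybe,
        category=category,
    )


def verdicts_to_frame(verdicts: Sequence[ScaffoldVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold_id": [v.scaffold_id for v in verdicts],
            "ko_id": [v.ko_id for v in verdicts],
            "verdict": [v.verdict for v in verdicts],
            "is_edge": [v.features.is_edge for v in verdicts],
            "strand_switch_frac": [
                round(v.features.strand_switch_frac, 6) for v in verdicts
            ],
            "nonviral_density": [
                round(v.features.nonviral_density, 6) for v in verdicts
            ],
            "hallmark_flanked": [v.features.hallmark_flanked for v in verdicts],
            "hypothetical_frac": [
                round(v.features.hypothetical_frac, 6) for v in verdicts
            ],
            "reasons": [";".join(v.reasons) for v in verdicts],
        }
    )


def summaries_to_frame(summaries: Sequence[GeneCurationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ko_id": [s.ko_id for s in summaries],
            "n_scaffolds_detected": [s.n_scaffolds_detected for s in summaries],
            "n_inspected": [s.n_inspected for s in summaries],
            "n_true": [s.n_true for s in summaries],
            "n_false": [s.n_false for s in summaries],
            "n_maybe": [s.n_maybe for s in summaries],
            "category": [s.category for s in summaries],
        }
    )


def curate_scaffolds(
    maps: Sequence[ScaffoldMap], config: CurationConfig | None = None
) -> tuple[list[ScaffoldVerdict], list[GeneCurationSummary]]:
    """Score every scaffold and summarize per focal KO (sorted by KO)."""
    config = config or CurationConfig()
    verdicts = [score_scaffold(m, config) for m in maps]
    by_ko: dict[str, list[ScaffoldVerdict]] = {}
    for v in verdicts:
        by_ko.setdefault(v.ko_id, []).append(v)
    summaries = [
        summarize_gene(vs, config=config) for _, vs in sorted(by_ko.items())
    ]
    return verdicts, summaries
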