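"""Readers for the annotation/metadata TSV dialects and presence-matrix assembly.

The central product is :class:`PresenceMatrix`: a boolean gene-by-phage
detection matrix joined to a per-phage host-trait label (does any predicted
host form endospores?).  It carries the four counts of the hypergeometric
enrichment test: ``N`` phages surveyed, ``K`` of them infecting
spore-formers, per-gene ``n`` detections and ``k`` detections among
spore-host phages.

Conventions
-----------
* Coordinates are 1-based, inclusive (GFF-style).
* Strand is ``+`` or ``-``; the Unicode minus sign is normalized on read.
* A phage with several predicted hosts counts as a spore-host phage if ANY
  host is a spore-former: a phage-carried gene can only act on sporulation
  if at least one of its hosts sporulates.
* Phages with no host prediction are excluded from the test universe; the
  number excluded is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Columns every annotation table must name.  ``phage_id`` is optional at
#: read time (scaffold-only inputs have no phage) but is required before a
#: presence matrix can be built.
REQUIRED_ANNOTATION_COLUMNS = (
    "gene_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "ko_id",
    "description",
)

_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f"}


def _parse_bool(value: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValidationError(f"{column}: cannot interpret {value!r} as a boolean")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene call on one scaffold (a row of a DRAM-v-like table)."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    ko_id: Optional[str] = None
    description: str = ""
    phage_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", self.strand.replace("−", "-"))
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"strand: expected '+' or '-', got {self.strand!r} "
                f"(gene {self.gene_id})"
            )
        if self.start > self.end:
            raise ValidationError(
                f"start/end: start {self.start} > end {self.end} "
                f"(gene {self.gene_id})"
            )
        if self.start < 1:
            raise ValidationError(
                f"start: coordinates are 1-based, got {self.start} "
                f"(gene {self.gene_id})"
            )


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One KO of the screened gene catalog with its regulatory type.

    ``reg_type`` is "R" (regulatory), "NR" (nonregulatory), "R+NR" (dual
    role, e.g. the sporulation-initiation inhibitor / partitioning protein
    Soj), or "U" (uncharacterized).
    """

    ko_id: str
    locus: str
    gene_name: str
    reg_type: str
    function: str
    is_sporulation: bool = True

    VALID_TYPES = ("R", "NR", "R+NR", "U")

    def __post_init__(self) -> None:
        object.__setattr__(self, "reg_type", self.reg_type.upper().replace(" ", ""))
        if self.reg_type not in self.VALID_TYPES:
            raise ValidationError(
                f"reg_type: {self.reg_type!r} not one of {self.VALID_TYPES} "
                f"(KO {self.ko_id})"
            )


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_annotations(path) -> list[GeneAnnotation]:
    """Read a tab-separated annotation table into :class:`GeneAnnotation` rows.

    Rows with an empty ``ko_id`` are retained with ``ko_id=None``.  Extra
    columns are ignored.  Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (with the 1-based file line) for bad rows.
    """
    frame = _read_tsv(path)
    _require_columns(frame, REQUIRED_ANNOTATION_COLUMNS, f"annotations {path}")
    has_phage = "phage_id" in frame.columns
    records: list[GeneAnnotation] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"line {line}: start/end must be integers ({exc})"
            ) from exc
        ko = getattr(row, "ko_id").strip()
        phage = getattr(row, "phage_id").strip() if has_phage else ""
        try:
            records.append(
                GeneAnnotation(
                    gene_id=getattr(row, "gene_id"),
                    scaffold_id=getattr(row, "scaffold_id"),
                    start=start,
                    end=end,
                    strand=getattr(row, "strand"),
                    ko_id=ko or None,
                    description=getattr(row, "description"),
                    phage_id=phage or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    return records


def annotations_to_frame(annotations: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Serialize annotations back to the tabular dialect (round-trip safe)."""
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "scaffold_id": [a.scaffold_id for a in annotations],
            "phage_id": [a.phage_id or "" for a in annotations],
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "strand": [a.strand for a in annotations],
            "ko_id": [a.ko_id or "" for a in annotations],
            "description": [a.description for a in annotations],
        }
    )


def read_hosts(path) -> pd.DataFrame:
    """Read the host trait table (host_id, taxon, is_spore_former)."""
    frame = _read_tsv(path)
    _require_columns(frame, ("host_id", "taxon", "is_spore_former"), f"hosts {path}")
    frame = frame.copy()
    frame["is_spore_former"] = [
        _parse_bool(v, "is_spore_former") for v in frame["is_spore_former"]
    ]
    return frame


def read_phages(path) -> pd.DataFrame:
    """Read the phage->predicted-host table; one row per (phage, host) pair."""
    frame = _read_tsv(path)
    _require_columns(frame, ("phage_id", "host_id"), f"phages {path}")
    return frame


def read_catalog(path) -> list[GeneCatalogEntry]:
    """Read a gene catalog TSV (ko_id, locus, gene_name, reg_type, function,
    is_sporulation); consecutive rows with a blank ko_id inherit the KO above
    (multiple loci can map to one KO)."""
    frame = _read_tsv(path)
    _require_columns(
        frame,
        ("ko_id", "locus", "gene_name", "reg_type", "function", "is_sporulation"),
        f"catalog {path}",
    )
    entries: list[GeneCatalogEntry] = []
    last_ko = ""
    for _, row in frame.iterrows():
        ko = row["ko_id"].strip() or last_ko
        if not ko:
            raise ValidationError("catalog: first row has an empty ko_id")
        last_ko = ko
        entries.append(
            GeneCatalogEntry(
                ko_id=ko,
                locus=row["locus"],
                gene_name=row["gene_name"],
                reg_type=row["reg_type"],
                function=row["function"],
                is_sporulation=_parse_bool(row["is_sporulation"], "is_sporulation"),
            )
        )
    return entries


def load_default_catalog() -> list[GeneCatalogEntry]:
    """The packaged sporulation-gene catalog (B. subtilis / C. difficile KOs)."""
    ref = resources.files("sporeamg.data").joinpath("sporulation_catalog.tsv")
    with resources.as_file(ref) as path:
        return read_catalog(path)


def catalog_ko_order(catalog: Sequence[GeneCatalogEntry]) -> list[str]:
    """Distinct KO ids in catalog order (the gene axis of the matrix)."""
    seen: dict[str, None] = {}
    for entry in catalog:
        seen.setdefault(entry.ko_id, None)
    return list(seen)


@dataclass
class PresenceMatrix:
    """Boolean KO-by-phage detection matrix with host-trait labels.

    ``present[g, j]`` is True iff at least one annotation of KO ``genes[g]``
    lies on any scaffold of phage ``phages[j]``.  ``N`` is the number of
    phages surveyed (including phages with zero catalog hits) and ``K`` the
    number whose predicted host set contains a spore-former.
    """

    genes: list[str]
    phages: list[str]
    present: np.ndarray
    spore_host: np.ndarray
    n_excluded_no_host: int = 0
    _gene_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.spore_host = np.asarray(self.spore_host, dtype=bool)
        if self.present.shape != (len(self.genes), len(self.phages)):
            raise ValidationError(
                f"present: shape {self.present.shape} does not match "
                f"{len(self.genes)} genes x {len(self.phages)} phages"
            )
        if self.spore_host.shape != (len(self.phages),):
            raise ValidationError("spore_host: length does not match phage list")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def N(self) -> int:
        return len(self.phages)

    @property
    def K(self) -> int:
        return int(self.spore_host.sum())

    def gene_counts(self, ko_id: str) -> tuple[int, int]:
        """Return (n, k): total detections and detections in spore-host phages."""
        row = self.present[self._gene_index[ko_id]]
        return int(row.sum()), int(row[self.spore_host].sum())


def build_presence_matrix(
    annotations: Sequence[GeneAnnotation],
    phages: pd.DataFrame,
    hosts: pd.DataFrame,
    catalog: Sequence[GeneCatalogEntry],
) -> PresenceMatrix:
    """Assemble the gene-by-phage presence matrix for the catalog KOs.

    Duplicate detections of one KO in one phage collapse to a single True
    cell.  Every phage in the phage table (with a known host) contributes to
    ``N`` even with zero hits.  Unknown phage or host ids raise
    :class:`ReferentialIntegrityError`.
    """
    host_trait = dict(zip(hosts["host_id"], hosts["is_spore_former"]))

    bad_hosts = sorted(
        {h for h in phages["host_id"] if h.strip() and h not in host_trait}
    )
    if bad_hosts:
        raise ReferentialIntegrityError(
            f"phage table references unknown host_id(s): {bad_hosts}"
        )

    # spore_host = OR over predicted hosts; phages without any host prediction
    # are dropped from the universe (count logged).
    spore_by_phage: dict[str, bool] = {}
    no_host: set[str] = set()
    for pid, hid in zip(phages["phage_id"], phages["host_id"]):
        if not hid.strip():
            no_host.add(pid)
            continue
        spore_by_phage[pid] = spore_by_phage.get(pid, False) or bool(host_trait[hid])
    no_host -= set(spore_by_phage)
    if no_host:
        logger.info(
            "excluding %d phage(s) with no host prediction from the test universe",
            len(no_host),
        )

    phage_order = [
        p for p in dict.fromkeys(phages["phage_id"]) if p in spore_by_phage
    ]
    phage_index = {p: j for j, p in enumerate(phage_order)}

    known = set(phage_index) | no_host
    bad_phages = sorted(
        {a.phage_id for a in annotations if a.phage_id and a.phage_id not in known}
    )
    if bad_phages:
        raise ReferentialIntegrityError(
            f"annotations reference unknown phage_id(s): {bad_phages}"
        )

    genes = catalog_ko_order(catalog)
    gene_index = {g: i for i, g in enumerate(genes)}
    present = np.zeros((len(genes), len(phage_order)), dtype=bool)
    for ann in annotations:
        if ann.ko_id is None or ann.phage_id is None:
            continue
        gi = gene_index.get(ann.ko_id)
        pj = phage_index.get(ann.phage_id)
        if gi is not None and pj is not None:
            present[gi, pj] = True

    spore_vec = np.array([spore_by_phage[p] for p in phage_order], dtype=bool)
    return PresenceMatrix(
        genes=genes,
        phages=phage_order,
        present=present,
        spore_host=spore_vec,
        n_excluded_no_host=len(no_host),
    )
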