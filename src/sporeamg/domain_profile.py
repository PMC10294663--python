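"""Alignment-coverage profiles and domain-truncation calls.

Response regulators such as spo0A have a two-domain architecture: an
N-terminal receiver domain (phosphorylation input) and a C-terminal
DNA-binding effector domain (output).  Given a multiple sequence alignment
of homologs labeled by source group (e.g. "bacteria" vs "virome"), this
module computes per-group, per-column non-gap coverage and calls each
sequence as full-length, effector-only (the receiver domain is missing), or
other.  An effector-only homolog is a candidate constitutive regulator: it
keeps the DNA-binding output but has lost the domain that couples activity
to the host's phosphorelay signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

#: Accepted gap characters; normalized to "-" internally.
GAP_CHARS = ("-", ".", "−")

Span = tuple[int, int]  # 1-based inclusive alignment columns


def _normalize(seq: str) -> str:
    for ch in GAP_CHARS[1:]:
        seq = seq.replace(ch, "-")
    return seq.upper()


@dataclass
class GroupedAlignment:
    """Equal-length aligned sequences with a source group per sequence."""

    ids: list[str]
    seqs: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        if not self.seqs:
            raise ValidationError("alignment is empty")
        self.seqs = [_normalize(s) for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValidationError(f"sequences have unequal lengths {sorted(lengths)}")
        unlabeled = [i for i in self.ids if i not in self.labels]
        if unlabeled:
            raise ValidationError(f"unlabeled sequence(s): {unlabeled}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.labels[i] for i in self.ids))

    @classmethod
    def from_fasta(cls, fasta_path, labels: Mapping[str, str] | str) -> "GroupedAlignment":
        """Load an aligned FASTA; ``labels`` is a mapping or a TSV path with
        columns sequence_id, group."""
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if isinstance(labels, (str,)) or hasattr(labels, "read_text"):
            table = pd.read_csv(labels, sep="\t", dtype=str)
            label_map = dict(zip(table["sequence_id"], table["group"]))
        else:
            label_map = dict(labels)
        return cls(
            ids=[r.id for r in records],
            seqs=[str(r.seq) for r in records],
            labels=label_map,
        )

    def to_fasta(self, fasta_path, labels_path=None) -> None:
        with open(fasta_path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")
        if labels_path is not None:
            pd.DataFrame(
                {"sequence_id": self.ids, "group": [self.labels[i] for i in self.ids]}
            ).to_csv(labels_path, sep="\t", index=False)


@dataclass(frozen=True)
class DomainSpans:
    """Receiver and effector domain extents in alignment-column coordinates
    (1-based inclusive); receiver must precede the effector, disjointly."""

    receiver: Span
    effector: Span

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("receiver", self.receiver), ("effector", self.effector)):
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} span {lo}-{hi} is not a valid interval")
        if self.receiver[1] >= self.effector[0]:
            raise ValidationError(
                f"spans must be disjoint and ordered receiver-before-effector: "
                f"receiver {self.receiver}, effector {self.effector}"
            )

    def validate_against(self, aln_length: int) -> None:
        if self.effector[1] > aln_length:
            raise ValidationError(
                f"effector span end {self.effector[1]} exceeds alignment "
                f"length {aln_length}"
            )


@dataclass(frozen=True)
class TruncationThresholds:
    present: float = 0.5  # span coverage at or above which a domain is present
    absent: float = 0.1  # span coverage at or below which a domain is absent

    def __post_init__(self) -> None:
        if not 0.0 <= self.absent < self.present <= 1.0:
            raise ValidationError(
                f"thresholds must satisfy 0 <= absent < present <= 1, got "
                f"absent={self.absent}, present={self.present}"
            )


@dataclass(frozen=True)
class TruncationCall:
    sequence_id: str
    group: str
    coverage_receiver: float
    coverage_effector: float
    call: str  # "full_length" | "effector_only" | "other"


def column_coverage(aln: GroupedAlignment) -> pd.DataFrame:
    """Percent non-gap characters per group per column.

    Returns a DataFrame indexed by group with one column per alignment
    position (1-based); values are in [0, 100].
    """
    mat = np.frombuffer(
        "".join(aln.seqs).encode("ascii"), dtype="S1"
    ).reshape(len(aln.seqs), aln.length)
    nongap = mat != b"-"
    group_of = np.array([aln.labels[i] for i in aln.ids])
    rows = {}
    for g in aln.groups:
        sel = nongap[group_of == g]
        rows[g] = 100.0 * sel.mean(axis=0)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = range(1, aln.length + 1)
    frame.index.name = "group"
    return frame


def span_coverage(seq: str, span: Span) -> float:
    """Fraction of non-gap characters of ``seq`` within a 1-based span."""
    lo, hi = span
    if not (1 <= lo <= hi <= len(seq)):
        raise ValidationError(
            f"span {lo}-{hi} out of bounds for sequence of length {len(seq)}"
        )
    window = _normalize(seq)[lo - 1 : hi]
    return sum(c != "-" for c in window) / (hi - lo + 1)


def call_truncation(
    aln: GroupedAlignment,
    spans: DomainSpans,
    thresholds: TruncationThresholds | None = None,
) -> list[TruncationCall]:
    """Call each sequence full_length / effector_only / other.

    full_length: both domains present; effector_only: effector present and
    receiver absent; everything in between is "other".
    """
    thresholds = thresholds or TruncationThresholds()
    spans.validate_against(aln.length)
    calls = []
    for sid, seq in zip(aln.ids, aln.seqs):
        cov_r = span_coverage(seq, spans.receiver)
        cov_e = span_coverage(seq, spans.effector)
        if cov_r >= thresholds.present and cov_e >= thresholds.present:
            call = "full_length"
        elif cov_e >= thresholds.present and cov_r <= thresholds.absent:
            call = "effector_only"
        else:
            call = "other"
        calls.append(
            TruncationCall(
                sequence_id=sid,
                group=aln.labels[sid],
                coverage_receiver=cov_r,
                coverage_effector=cov_e,
                call=call,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[TruncationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [c.sequence_id for c in calls],
            "group": [c.group for c in calls],
            "coverage_receiver": [round(c.coverage_receiver, 6) for c in calls],
            "coverage_effector": [round(c.coverage_effector, 6) for c in calls],
            "call": [c.call for c in calls],
        }
    )


def plot_coverage(coverage: pd.DataFrame, spans: DomainSpans, path) -> None:
    """Render the per-group coverage profile with domain spans shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "sporeamg"  # deterministic SVG ids

    fig, ax = plt.subplots(figsize=(8, 3))
    for g in coverage.index:
        ax.plot(coverage.columns, coverage.loc[g], label=g)
    for (lo, hi), color, name in (
        (spans.receiver, "#c6dbef", "receiver"),
        (spans.effector, "#fdd0a2", "effector"),
    ):
        ax.axvspan(lo, hi, color=color, alpha=0.5)
        ax.text((lo + hi) / 2, 103, name, ha="center", fontsize=8)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("% non-gap")
    ax.set_ylim(0, 112)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    # strip the creation date so outputs are byte-reproducible
    metadata = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, metadata=metadata)
    plt.close(fig)
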