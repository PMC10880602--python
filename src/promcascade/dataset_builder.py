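"""Balanced promoter / non-promoter dataset construction.

Positives are the last 60 nt of a TSS- or CDS-anchored upstream region
(promoter positions −59..+1; the numbering has no 0, so the stated "−60 to
+1" span is exactly 60 nucleotides).  Negatives are 60-nt windows sampled at
a uniformly random start offset between +1 and +500 in the matching
downstream region, clamped when the downstream sequence is shorter.  Each
usable record contributes one positive and one negative, giving a 1:1 class
balance by construction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dds_encoding import DDSTable, encode_batch
from .errors import EmptyDatasetError, TooShortError

logger = logging.getLogger(__name__)

WINDOW = 60            # promoter window width, nt
MAX_NEG_OFFSET = 500   # largest 1-based downstream start offset for negatives


@dataclass
class AnchoredSequence:
    """An upstream/downstream pair around one anchor (+1 of a TSS or CDS start).

    Both strings are 5'→3' on the gene's strand; the caller resolves strand
    (reverse-complementing minus-strand genes) before construction, mirroring
    the RSAT upstream-retrieval convention.
    """

    id: str
    upstream: str
    downstream: str
    organism: str = ""
    anchor_kind: str = "TSS"  # or "CDS_start"


@dataclass
class DatasetRecord:
    id: str
    sequence: str
    label: int
    organism: str = ""
    source_id: str = ""
    offset: int | None = None  # negatives: 1-based downstream start


@dataclass
class PromoterDataset:
    """Labeled fixed-width windows; label 1 = promoter, 0 = background."""

    records: list[DatasetRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(Counter(r.label for r in self.records))

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def encode(self, table: DDSTable | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Feature matrix, labels and ids, row-aligned."""
        X, ids = encode_batch([(r.id, r.sequence) for r in self.records], table)
        return X, self.labels(), ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids(),
                "sequence": self.sequences(),
                "label": self.labels(),
                "organism": [r.organism for r in self.records],
                "source_id": [r.source_id for r in self.records],
            }
        )

    def subset(self, indices: Sequence[int]) -> "PromoterDataset":
        return PromoterDataset(records=[self.records[i] for i in indices])


def extract_promoter_window(rec: AnchoredSequence, window: int = WINDOW) -> str:
    """The ``window`` nucleotides of the upstream string ending at the anchor."""
    if len(rec.upstream) < window:
        raise TooShortError(
            f"record {rec.id!r}: upstream length {len(rec.upstream)} < {window}"
        )
    return rec.upstream[-window:].upper()


def sample_negative(
    rec: AnchoredSequence,
    rng_seed: int | np.random.Generator,
    window: int = WINDOW,
    max_offset: int = MAX_NEG_OFFSET,
) -> tuple[str, int]:
    """A window-sized substring of the downstream region at a random offset.

    The 1-based start offset is uniform on ``[1, min(max_offset,
    len(downstream) − window + 1)]``; the upper bound is clamped for short
    downstream regions so usable records are not discarded.
    """
    if len(rec.downstream) < window:
        raise TooShortError(
            f"record {rec.id!r}: downstream length {len(rec.downstream)} < {window}"
        )
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    hi = min(max_offset, len(rec.downstream) - window + 1)
    offset = int(rng.integers(1, hi + 1))
    return rec.downstream[offset - 1 : offset - 1 + window].upper(), offset


def build_balanced_dataset(
    records: Iterable[AnchoredSequence],
    rng_seed: int,
    window: int = WINDOW,
    deduplicate: bool = True,
) -> PromoterDataset:
    """One positive and one negative window per usable anchored record.

    A record contributes only when both extractions succeed, so the classes
    stay 1:1 (a record whose downstream region is too short loses its positive
    as well).  Identical (sequence, label) duplicates — e.g. operon genes
    sharing a TSS — are dropped to prevent train/test leakage, and the larger
    class is then downsampled (seeded) to restore exact balance.  Skips are
    logged with their reason.
    """
    rng = np.random.default_rng(rng_seed)
    out: list[DatasetRecord] = []
    n_skipped = 0
    for rec in records:
        try:
            pos = extract_promoter_window(rec, window)
        except TooShortError as exc:
            logger.warning("skipping %s (positive): %s", rec.id, exc)
            n_skipped += 1
            continue
        try:
            neg, offset = sample_negative(rec, rng, window)
        except TooShortError as exc:
            logger.warning("skipping %s (negative; unmatched positive dropped): %s", rec.id, exc)
            n_skipped += 1
            continue
        out.append(DatasetRecord(f"{rec.id}|prom", pos, 1, rec.organism, rec.id))
        out.append(DatasetRecord(f"{rec.id}|neg", neg, 0, rec.organism, rec.id, offset))
    if not out:
        raise EmptyDatasetError(f"no usable records ({n_skipped} skipped)")
    if deduplicate:
        seen: set[tuple[str, int]] = set()
        deduped: list[DatasetRecord] = []
        for r in out:
            key = (r.sequence, r.label)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(r)
        n_dup = len(out) - len(deduped)
        if n_dup:
            logger.info("dropped %d duplicate (sequence, label) windows", n_dup)
        out = deduped
        # dedup can unbalance the classes; downsample the larger one
        by_label = {0: [r for r in out if r.label == 0], 1: [r for r in out if r.label == 1]}
        n_keep = min(len(by_label[0]), len(by_label[1]))
        if n_keep == 0:
            raise EmptyDatasetError("deduplication removed an entire class")
        balanced: list[DatasetRecord] = []
        for lab in (1, 0):
            group = by_label[lab]
            if len(group) > n_keep:
                keep_idx = np.sort(rng.choice(len(group), size=n_keep, replace=False))
                group = [group[i] for i in keep_idx]
            balanced.extend(group)
        out = balanced
    return PromoterDataset(records=out)


def split_train_test(
    ds: PromoterDataset, test_fraction: float, rng_seed: int
) -> tuple[PromoterDataset, PromoterDataset]:
    """Label-stratified split with disjoint ids, reproducible under seed."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=ds.labels(),
        random_state=int(rng_seed),
    )
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# I/O: paired FASTA, single TSV, dataset round-trip
# ---------------------------------------------------------------------------

def load_anchored_fasta(upstream_path, downstream_path, organism: str = "") -> list[AnchoredSequence]:
    """Paired FASTA files with matching ids → anchored records (id-intersection)."""
    ups = {r.id: str(r.seq) for r in SeqIO.parse(str(upstream_path), "fasta")}
    downs = {r.id: str(r.seq) for r in SeqIO.parse(str(downstream_path), "fasta")}
    missing = set(ups) ^ set(downs)
    if missing:
        logger.warning("%d ids present in only one of the paired FASTA files", len(missing))
    return [
        AnchoredSequence(id=k, upstream=ups[k], downstream=downs[k], organism=organism)
        for k in ups
        if k in downs
    ]


def load_anchored_tsv(path) -> list[AnchoredSequence]:
    """TSV with columns id, organism, upstream_seq, downstream_seq."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "organism", "upstream_seq", "downstream_seq"}
    if not required.issubset(df.columns):
        from .errors import FormatError

        raise FormatError(f"anchored TSV needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        AnchoredSequence(
            id=row.id, organism=row.organism, upstream=row.upstream_seq, downstream=row.downstream_seq
        )
        for row in df.itertuples()
    ]


def write_dataset(ds: PromoterDataset, outdir) -> dict[str, Path]:
    """Write sequences.fa + labels.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "sequences.fa"
    labels = outdir / "labels.tsv"
    with open(fasta, "w") as fh:
        for r in ds.records:
            fh.write(f">{r.id}\n{r.sequence}\n")
    ds.to_frame()[["id", "label"]].to_csv(labels, sep="\t", index=False)
    return {"fasta": fasta, "labels": labels}


def load_dataset(fasta_path, labels_path) -> PromoterDataset:
    """Round-trip loader for :func:`write_dataset` output (or a Zenodo-style deposit)."""
    labels = pd.read_csv(labels_path, sep="\t").set_index("id")["label"].to_dict()
    records = []
    for r in SeqIO.parse(str(fasta_path), "fasta"):
        if r.id not in labels:
            logger.warning("sequence %s has no label; skipped", r.id)
            continue
        records.append(DatasetRecord(id=r.id, sequence=str(r.seq).upper(), label=int(labels[r.id])))
    if not records:
        raise EmptyDatasetError("no labeled sequences found")
    return PromoterDataset(records=records)
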