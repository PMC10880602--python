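"""Genome-scale promoter annotation of upstream-region FASTA files.

Each upstream record (RSAT-style, up to 400 nt ending at the CDS start) is
reduced to its final 60 nt — the span that carries the core bacterial
promoter — encoded, and passed through the cascade.  Positive calls are
joined to a gene-annotation table so every predicted promoter is linked to
the function of the gene it putatively regulates.  The scan streams the
FASTA in batches, so memory is bounded by batch size rather than file size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cascade_model import CascadeModel, PredictionRecord
from .dds_encoding import encode_batch
from .errors import FormatError

logger = logging.getLogger(__name__)

WINDOW = 60

# optional RSAT-style header suffix: id|organism|contig:start-end(strand)
_HEADER_RE = re.compile(
    r"^(?P<id>\S+?)"
    r"(?:\|(?P<organism>[^|]*)\|(?P<contig>[^:|]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\))?$"
)


@dataclass
class UpstreamRecord:
    gene_id: str
    sequence: str
    organism: str = ""
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass
class PromoterCall:
    gene_id: str
    organism: str
    promoter_sequence: str
    prediction: PredictionRecord
    gene_product: str | None = None
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass
class ScanSummary:
    n_input: int = 0
    n_skipped: int = 0
    n_positive: int = 0
    n_negative: int = 0

    def check(self) -> None:
        assert self.n_positive + self.n_negative + self.n_skipped == self.n_input


def parse_header(header: str) -> UpstreamRecord:
    """First whitespace token is the gene id; an optional
    ``|organism|contig:start-end(strand)`` suffix supplies coordinates."""
    token = header.split()[0]
    m = _HEADER_RE.match(token)
    if m is None:  # fall back to the bare token as id
        return UpstreamRecord(gene_id=token, sequence="")
    d = m.groupdict()
    return UpstreamRecord(
        gene_id=d["id"],
        sequence="",
        organism=d["organism"] or "",
        contig=d["contig"],
        start=int(d["start"]) if d["start"] else None,
        end=int(d["end"]) if d["end"] else None,
        strand=d["strand"],
    )


def load_annotation(path) -> pd.DataFrame:
    """Annotation TSV with unique ``gene_id`` keys and a ``product`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "product" not in df.columns:
        raise FormatError(f"annotation table needs columns gene_id, product; got {list(df.columns)}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"annotation table has {int(dup.sum())} duplicate gene_id keys "
            f"(e.g. {df.loc[dup, 'gene_id'].iloc[0]!r})"
        )
    return df


def _batched(it: Iterator, size: int) -> Iterator[list]:
    batch: list = []
    for item in it:
        batch.append(item)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def scan_upstream_fasta(
    path,
    model: CascadeModel,
    annotation: pd.DataFrame | None = None,
    window: int = WINDOW,
    batch_size: int = 1024,
    keep_negatives: bool = True,
) -> tuple[list[PromoterCall], ScanSummary]:
    """Predict promoters on the final ``window`` nt of every upstream record.

    Records shorter than the window are skipped (never padded) and counted in
    the summary, which satisfies ``positives + negatives + skipped == inputs``.
    """
    summary = ScanSummary()
    calls: list[PromoterCall] = []
    try:
        reader = SeqIO.parse(str(path), "fasta")
        for batch in _batched(reader, batch_size):
            metas: list[UpstreamRecord] = []
            windows: list[tuple[str, str]] = []
            for rec in batch:
                summary.n_input += 1
                seq = str(rec.seq).upper()
                if len(seq) < window:
                    summary.n_skipped += 1
                    logger.warning("record %s is %d nt (< %d); skipped", rec.id, len(seq), window)
                    continue
                meta = parse_header(rec.description or rec.id)
                meta.sequence = seq[-window:]
                metas.append(meta)
                windows.append((meta.gene_id, meta.sequence))
            if not windows:
                continue
            X, ids = encode_batch(windows, model.table)
            preds = model.predict(X, ids)
            for meta, pred in zip(metas, preds):
                if pred.final_label == 1:
                    summary.n_positive += 1
                else:
                    summary.n_negative += 1
                    if not keep_negatives:
                        continue
                calls.append(
                    PromoterCall(
                        gene_id=meta.gene_id,
                        organism=meta.organism,
                        promoter_sequence=meta.sequence,
                        prediction=pred,
                        contig=meta.contig,
                        start=meta.start,
                        end=meta.end,
                        strand=meta.strand,
                    )
                )
    except ValueError as exc:
        raise FormatError(f"malformed FASTA near record {summary.n_input}: {exc}") from exc
    summary.check()
    if annotation is not None:
        join_annotation(calls, annotation)
    return calls, summary


def join_annotation(calls: list[PromoterCall], table: pd.DataFrame) -> int:
    """Left-join products onto calls by gene_id; unmatched ids get ``"NA"``.

    Returns the number of unmatched calls (also logged).
    """
    if table["gene_id"].duplicated().any():
        raise FormatError("annotation table has duplicate gene_id keys")
    products = table.set_index("gene_id")["product"].to_dict()
    n_missing = 0
    for call in calls:
        product = products.get(call.gene_id)
        if product is None:
            call.gene_product = "NA"
            n_missing += 1
        else:
            call.gene_product = str(product)
    if n_missing:
        logger.info("join_annotation: %d calls had no annotation entry", n_missing)
    return n_missing


def calls_to_frame(calls: Iterable[PromoterCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        p = c.prediction
        rows.append(
            {
                "gene_id": c.gene_id,
                "organism": c.organism,
                "promoter_sequence": c.promoter_sequence,
                "stage1_score": p.stage1_score,
                "stage1_label": p.stage1_label,
                "stage2_score": p.stage2_score,
                "stage2_label": p.stage2_label,
                "final_label": p.final_label,
                "gene_product": c.gene_product,
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(calls: Iterable[PromoterCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_positive_fasta(calls: Iterable[PromoterCall], path) -> int:
    """FASTA of positively called promoter windows; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for c in calls:
            if c.prediction.final_label == 1:
                fh.write(f">{c.gene_id}\n{c.promoter_sequence}\n")
                n += 1
    return n


def write_calls_bed(calls: Iterable[PromoterCall], path) -> int:
    """BED6 intervals (0-based half-open) for calls that carried coordinates.

    The promoter window is the final 60 nt of the upstream interval on its
    strand; score = stage-1 probability × 1000, truncated.  Returns the number
    of lines written.
    """
    n = 0
    with open(path, "w") as fh:
        for c in calls:
            if c.contig is None or c.start is None or c.end is None:
                continue
            if c.prediction.final_label != 1:
                continue
            w = len(c.promoter_sequence)
            # headers carry 1-based inclusive upstream coordinates
            if c.strand == "-":
                bed_start, bed_end = c.start - 1, c.start - 1 + w
            else:
                bed_start, bed_end = c.end - w, c.end
            score = int(c.prediction.stage1_score * 1000)
            fh.write(
                f"{c.contig}\t{bed_start}\t{bed_end}\t{c.gene_id}\t{score}\t{c.strand or '+'}\n"
            )
            n += 1
    return n
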