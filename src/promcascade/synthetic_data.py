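"""Synthetic promoter benchmarks with planted, tunable σ70-style signals.

Positives are i.i.d. background sequences (specified GC content) carrying the
canonical −10 (TATAAT) and −35 (TTGACA) hexamers, each independently mutated
per position at a configurable rate; a ``weak_fraction`` subpopulation uses an
elevated rate, degrading its motifs so a first-stage classifier misses some of
them — the material the cascade's rescue path is designed for.  Negatives are
pure background.  Everything is reproducible from one seed, and a truth
manifest records every planted motif's position, realized sequence and
strength class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_builder import DatasetRecord, PromoterDataset
from .errors import ConfigError

BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Motif centers are given as dinucleotide-step positions in promoter
    coordinates (step *i* of a 60-nt window, 1-based from the 5' end, sits at
    position *i* − 60; the −10 box therefore centers on step −10).  Mutation
    rates are per motif position; ``weak_fraction`` of positives use
    ``weak_mutation_rate`` for both motifs instead.
    """

    n_per_class: int
    seed: int
    seq_length: int = 60
    background_gc: float = 0.5
    minus10_motif: str = "TATAAT"
    minus10_center: int = -10
    minus35_motif: str = "TTGACA"
    minus35_center: int = -35
    mutation_rate: float = 0.10
    weak_fraction: float = 0.0
    weak_mutation_rate: float = 0.45

    def __post_init__(self) -> None:
        for name in ("background_gc", "mutation_rate", "weak_fraction", "weak_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for motif, center in ((self.minus10_motif, self.minus10_center),
                              (self.minus35_motif, self.minus35_center)):
            start = _motif_start(motif, center, self.seq_length)
            if start < 0 or start + len(motif) > self.seq_length:
                raise ConfigError(
                    f"motif {motif!r} centered at step {center} does not fit in "
                    f"a {self.seq_length}-nt window"
                )


def _motif_start(motif: str, center_step: int, seq_length: int) -> int:
    """0-based start index so the motif's central dinucleotide step sits at
    ``center_step`` in promoter coordinates (step i displayed at i − length)."""
    center_index = seq_length + center_step          # 1-based step index
    start_1based = center_index - (len(motif) - 2) // 2
    return start_1based - 1


def _background(rng: np.random.Generator, n: int, length: int, gc: float) -> np.ndarray:
    """(n, length) array of base indices, i.i.d. with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def _mutate(motif_idx: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Redraw each position with prob ``rate`` uniformly over ACGT.

    Redrawing (rather than forcing a different base) makes rate 1.0 exactly
    the uniform background, so classifier accuracy decays to chance as the
    rate rises instead of re-learning an anti-consensus signal.
    """
    out = motif_idx.copy()
    hit = rng.random(len(out)) < rate
    if hit.any():
        out[hit] = rng.integers(0, 4, size=int(hit.sum()))
    return out


def _to_str(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def generate(config: SyntheticConfig) -> tuple[PromoterDataset, list[dict]]:
    """Build a balanced synthetic dataset plus its truth manifest.

    Returns the dataset (``n_per_class`` positives then negatives, all of
    ``seq_length`` nt) and a manifest with one entry per positive recording
    the planted motifs' 0-based starts, realized sequences and whether the
    record belongs to the weak subpopulation.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    m10 = np.array([BASES.index(b) for b in config.minus10_motif.upper()])
    m35 = np.array([BASES.index(b) for b in config.minus35_motif.upper()])
    s10 = _motif_start(config.minus10_motif, config.minus10_center, L)
    s35 = _motif_start(config.minus35_motif, config.minus35_center, L)

    pos = _background(rng, config.n_per_class, L, config.background_gc)
    n_weak = int(round(config.n_per_class * config.weak_fraction))
    weak = np.zeros(config.n_per_class, dtype=bool)
    if n_weak:
        weak[rng.choice(config.n_per_class, size=n_weak, replace=False)] = True

    manifest: list[dict] = []
    records: list[DatasetRecord] = []
    width = max(4, len(str(config.n_per_class)))
    for i in range(config.n_per_class):
        rate = config.weak_mutation_rate if weak[i] else config.mutation_rate
        r35 = _mutate(m35, rate, rng)
        r10 = _mutate(m10, rate, rng)
        pos[i, s35 : s35 + len(m35)] = r35
        pos[i, s10 : s10 + len(m10)] = r10
        rid = f"pos_{i:0{width}d}"
        records.append(DatasetRecord(id=rid, sequence=_to_str(pos[i]), label=1,
                                     organism="synthetic"))
        manifest.append(
            {
                "id": rid,
                "minus10_start": s10,
                "minus10_realized": _to_str(r10),
                "minus35_start": s35,
                "minus35_realized": _to_str(r35),
                "strength": "weak" if weak[i] else "strong",
            }
        )
    neg = _background(rng, config.n_per_class, L, config.background_gc)
    for i in range(config.n_per_class):
        records.append(DatasetRecord(id=f"neg_{i:0{width}d}", sequence=_to_str(neg[i]),
                                     label=0, organism="synthetic"))
    return PromoterDataset(records=records), manifest


@dataclass
class SyntheticGenome:
    """Upstream-region fixture for the genome scanner."""

    upstream: list[tuple[str, str]]        # (gene_id, 400-nt sequence)
    annotation: pd.DataFrame               # gene_id, product
    truth: set[str] = field(default_factory=set)  # gene_ids carrying a planted promoter

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "upstream.fa"
        ann = outdir / "annotation.tsv"
        truth = outdir / "truth.tsv"
        with open(fasta, "w") as fh:
            for gid, seq in self.upstream:
                fh.write(f">{gid}\n{seq}\n")
        self.annotation.to_csv(ann, sep="\t", index=False)
        pd.DataFrame({"gene_id": sorted(self.truth)}).to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "annotation": ann, "truth": truth}


def generate_upstream_genome(
    config: SyntheticConfig,
    n_genes: int,
    promoter_fraction: float,
    seed: int,
    upstream_length: int = 400,
) -> SyntheticGenome:
    """Upstream FASTA fixture whose final 60 nt carry (or lack) a planted promoter.

    ``int(floor(n_genes * promoter_fraction + 0.5))`` genes (chosen by the
    seeded rng) get a positive window; the rest get background.  Every record
    is ``upstream_length`` nt, emulating RSAT's −400..+1 exports.
    """
    if not 0.0 <= promoter_fraction <= 1.0:
        raise ConfigError(f"promoter_fraction must be in [0, 1], got {promoter_fraction}")
    if upstream_length < config.seq_length:
        raise ConfigError("upstream_length must be >= the promoter window length")
    rng = np.random.default_rng(seed)
    n_prom = int(np.floor(n_genes * promoter_fraction + 0.5))
    prom_genes = set(rng.choice(n_genes, size=n_prom, replace=False).tolist())

    window_cfg = SyntheticConfig(
        n_per_class=max(n_prom, n_genes - n_prom, 1),
        seed=int(rng.integers(0, 2**31 - 1)),
        seq_length=config.seq_length,
        background_gc=config.background_gc,
        minus10_motif=config.minus10_motif,
        minus10_center=config.minus10_center,
        minus35_motif=config.minus35_motif,
        minus35_center=config.minus35_center,
        mutation_rate=config.mutation_rate,
        weak_fraction=config.weak_fraction,
        weak_mutation_rate=config.weak_mutation_rate,
    )
    windows, _ = generate(window_cfg)
    pos_windows = [r.sequence for r in windows.records if r.label == 1]
    neg_windows = [r.sequence for r in windows.records if r.label == 0]

    upstream: list[tuple[str, str]] = []
    truth: set[str] = set()
    products = []
    flank = upstream_length - config.seq_length
    pi = ni = 0
    width = max(4, len(str(n_genes)))
    for g in range(n_genes):
        gid = f"gene_{g:0{width}d}"
        pad = _to_str(_background(rng, 1, flank, config.background_gc)[0]) if flank else ""
        if g in prom_genes:
            window = pos_windows[pi]
            pi += 1
            truth.add(gid)
            products.append("sigma70-dependent synthetic gene")
        else:
            window = neg_windows[ni]
            ni += 1
            products.append("constitutive synthetic gene")
        upstream.append((gid, pad + window))
    annotation = pd.DataFrame({"gene_id": [g for g, _ in upstream], "product": products})
    return SyntheticGenome(upstream=upstream, annotation=annotation, truth=truth)
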