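"""Per-(site, read) feature encoding.

Two fixed-shape matrices are built for every candidate site in every read
that covers it:

* the **raw-signal feature**, a ``5 x (5*L)`` matrix (``5 x 325`` at the
  default ``L = 65``): rows 1-4 are the one-hot encoding of the 5-mer with
  each base's column repeated ``L`` times in place, row 5 is, per base, a
  random order-preserving selection of ``L`` of that base's
  median/MAD-normalized current values (zero-padded on the right when the
  base has fewer than ``L`` signals);
* the **basecalling-error feature**, an ``8 x 5`` matrix: per base, the
  reference one-hot (rows 1-4), the scaled basecall quality (row 5),
  mismatch and deletion indicators (rows 6-7) and the count of inserted
  bases anchored at that position (row 8).

Signals are normalized per read (median shift, MAD scale) before any
sampling, so the features are invariant to affine transforms of the raw
current trace.  The per-base signal sampler is seeded per
(read, transcript, site) by hashing with the global seed, making
extraction deterministic and order-independent.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import h5py
import numpy as np

from m6aduet.io import (
    BaseAlignmentRecord,
    CandidateSite,
    Event,
    EventAlignedRead,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class DegenerateSignalError(ValueError):
    """A read's signals have zero median absolute deviation (constant trace)."""


class SiteCoverageError(ValueError):
    """A read does not fully cover the 5-mer of a candidate site."""


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    L
        signals kept per base (the fixed signal length); 65 by default.
    seed
        global seed hashed with each (read, site) key to seed its sampler.
    quality_scale
        Phred quality divisor; qualities map to [0, 1] via clipping.
    """

    L: int = 65
    seed: int = 0
    quality_scale: float = 40.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.quality_scale <= 0:
            raise ValueError("quality_scale must be positive")


@dataclass
class SiteReadFeatures:
    """The two encoded matrices for one candidate site in one read."""

    transcript_id: str
    position: int
    read_id: str
    raw_signal_matrix: np.ndarray  # (5, 5*L) float32
    error_matrix: np.ndarray  # (8, 5) float32
    label: int | None = None  # 1 = m6A, for training

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.transcript_id, self.position, self.read_id)


def normalize_read_signals(read: EventAlignedRead) -> EventAlignedRead:
    """Median-shift / MAD-scale all signals of a read (statistics computed once
    over the whole read, not per base)."""
    med, mad = read.read_median, read.read_mad
    if mad <= 0:
        raise DegenerateSignalError(
            f"read {read.read_id}: constant signal (MAD = 0), cannot normalize"
        )
    events = [
        Event(ev.ref_position, ev.ref_base, tuple((s - med) / mad for s in ev.signals))
        for ev in read.events
    ]
    return EventAlignedRead(read.read_id, read.transcript_id, events)


def sample_base_signals(signals, L: int, rng: np.random.Generator) -> np.ndarray:
    """Select ``L`` of a base's signal values.

    With ``>= L`` values, ``L`` are drawn uniformly without replacement and
    returned in their original temporal order (the sequential information of
    the trace is preserved); with fewer, all values are kept and zeros are
    appended on the right.
    """
    sig = np.asarray(signals, dtype=np.float32)
    if sig.size == 0:
        raise ValueError("empty signal list")
    if L < 1:
        raise ValueError("L must be >= 1")
    if sig.size >= L:
        idx = rng.choice(sig.size, size=L, replace=False)
        idx.sort()
        return sig[idx]
    return np.concatenate([sig, np.zeros(L - sig.size, dtype=np.float32)])


def encode_fivemer_onehot(fivemer: str) -> np.ndarray:
    """One-hot encode a 5-mer as a 4x5 matrix, channel order A, C, G, T."""
    if len(fivemer) != 5:
        raise ValueError(f"expected a 5-mer, got {fivemer!r}")
    out = np.zeros((4, 5), dtype=np.float32)
    for j, base in enumerate(fivemer):
        try:
            out[_BASE_INDEX[base], j] = 1.0
        except KeyError:
            raise ValueError(f"non-ACGT character {base!r} in 5-mer {fivemer!r}") from None
    return out


def site_rng(seed: int, read_id: str, transcript_id: str, position: int) -> np.random.Generator:
    """Deterministic per-(read, site) generator: extraction order does not
    affect which signals are sampled."""
    digest = hashlib.sha256(
        f"{seed}\x1f{read_id}\x1f{transcript_id}\x1f{position}".encode()
    ).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:8], "little")))


def build_raw_signal_feature(
    read: EventAlignedRead,
    site: CandidateSite,
    cfg: FeatureConfig = FeatureConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build the ``5 x (5*L)`` raw-signal matrix for one site in one read.

    The read must already be normalized (see :func:`normalize_read_signals`)
    and must cover positions ``site.position - 2 .. site.position + 2``.
    """
    if rng is None:
        rng = site_rng(cfg.seed, read.read_id, site.transcript_id, site.position)
    by_pos = read.events_by_position()
    positions = range(site.position - 2, site.position + 3)
    try:
        events = [by_pos[p] for p in positions]
    except KeyError as exc:
        raise SiteCoverageError(
            f"read {read.read_id} does not cover position {exc.args[0]} of site "
            f"{site.transcript_id}:{site.position}"
        ) from None
    fivemer = "".join(ev.ref_base for ev in events)
    onehot = encode_fivemer_onehot(fivemer)
    L = cfg.L
    expanded = np.repeat(onehot, L, axis=1)  # each base's column, L times in place
    signal_row = np.concatenate([sample_base_signals(ev.signals, L, rng) for ev in events])
    return np.vstack([expanded, signal_row[None, :]]).astype(np.float32)


def build_error_feature(
    records: Iterable[BaseAlignmentRecord],
    site: CandidateSite,
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Build the ``8 x 5`` basecalling-error matrix for one site in one read.

    ``records`` must cover the five reference positions of the 5-mer
    (deletions supply deletion-status records).  Per column: reference-base
    one-hot (rows 1-4), quality scaled by ``cfg.quality_scale`` and clipped
    to [0, 1] (0 for deletions), mismatch indicator, deletion indicator,
    insertion count.
    """
    by_pos = {rec.ref_position: rec for rec in records}
    out = np.zeros((8, 5), dtype=np.float32)
    for j, pos in enumerate(range(site.position - 2, site.position + 3)):
        rec = by_pos.get(pos)
        if rec is None:
            raise SiteCoverageError(
                f"missing alignment record at {site.transcript_id}:{pos} for site "
                f"{site.transcript_id}:{site.position}"
            )
        out[_BASE_INDEX[rec.ref_base], j] = 1.0
        if rec.status == "deletion":
            out[4, j] = 0.0
            out[6, j] = 1.0
        else:
            out[4, j] = min(max(rec.base_quality / cfg.quality_scale, 0.0), 1.0)
            if rec.status == "mismatch":
                out[5, j] = 1.0
        out[7, j] = rec.insertion_count
    return out


def extract_site_read_features(
    reads: Iterable[EventAlignedRead],
    alignments: Iterable[BaseAlignmentRecord],
    sites: Iterable[CandidateSite],
    cfg: FeatureConfig = FeatureConfig(),
    labels: Mapping[tuple[str, int, str], int] | None = None,
    tally: dict | None = None,
) -> Iterator[SiteReadFeatures]:
    """Join reads, alignments and candidate sites into feature records.

    One :class:`SiteReadFeatures` is yielded per (site, read) pair for which
    both matrices are constructible; pairs with missing event or alignment
    coverage are skipped and tallied, degenerate (constant-signal) reads are
    dropped and tallied.  Deterministic given ``cfg.seed``.

    ``labels`` optionally maps ``(transcript_id, position, read_id)`` to a
    binary methylation label attached to each record.
    """
    if tally is None:
        tally = {}
    tally.setdefault("pairs_emitted", 0)
    tally.setdefault("pairs_skipped", 0)
    tally.setdefault("reads_degenerate", 0)

    sites_by_tx: dict[str, list[CandidateSite]] = {}
    for site in sites:
        sites_by_tx.setdefault(site.transcript_id, []).append(site)

    aln_index: dict[tuple[str, str], dict[int, BaseAlignmentRecord]] = {}
    for rec in alignments:
        aln_index.setdefault((rec.read_id, rec.transcript_id), {})[rec.ref_position] = rec

    for read in reads:
        tx_sites = sites_by_tx.get(read.transcript_id)
        if not tx_sites:
            continue
        try:
            norm = normalize_read_signals(read)
        except DegenerateSignalError:
            tally["reads_degenerate"] += 1
            logger.warning("read %s dropped: constant signal", read.read_id)
            continue
        start, end = norm.span
        read_aln = aln_index.get((read.read_id, read.transcript_id), {})
        for site in tx_sites:
            if site.position - 2 < start or site.position + 3 > end:
                tally["pairs_skipped"] += 1
                continue
            try:
                raw = build_raw_signal_feature(norm, site, cfg)
                recs = [
                    read_aln[p]
                    for p in range(site.position - 2, site.position + 3)
                    if p in read_aln
                ]
                err = build_error_feature(recs, site, cfg)
            except SiteCoverageError:
                tally["pairs_skipped"] += 1
                continue
            label = labels.get((site.transcript_id, site.position, read.read_id)) if labels else None
            tally["pairs_emitted"] += 1
            yield SiteReadFeatures(site.transcript_id, site.position, read.read_id, raw, err, label)


# ---------------------------------------------------------------------------
# feature container (HDF5)


def stack_features(
    feats: Iterable[SiteReadFeatures],
) -> tuple[list[tuple[str, int, str]], np.ndarray, np.ndarray, np.ndarray]:
    """Stack a feature stream into arrays: keys, raw (N,5,5L), err (N,8,5),
    labels (N,) with -1 where no label is attached."""
    keys, raws, errs, labels = [], [], [], []
    for f in feats:
        keys.append(f.key)
        raws.append(f.raw_signal_matrix)
        errs.append(f.error_matrix)
        labels.append(-1 if f.label is None else int(f.label))
    if not keys:
        raise ValueError("no feature records to stack")
    return (
        keys,
        np.stack(raws).astype(np.float32),
        np.stack(errs).astype(np.float32),
        np.asarray(labels, dtype=np.int64),
    )


def save_features(path: str | Path, feats: Iterable[SiteReadFeatures]) -> int:
    """Write feature records to an HDF5 container; returns the record count.

    Layout: datasets ``raw`` (N,5,5L) f4, ``error`` (N,8,5) f4, ``label``
    (N,) i8 (-1 = unlabeled), and variable-length string datasets
    ``transcript_id``, ``read_id`` plus ``position`` (N,) i8.
    """
    keys, raw, err, label = stack_features(feats)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("raw", data=raw, compression="gzip")
        h5.create_dataset("error", data=err, compression="gzip")
        h5.create_dataset("label", data=label)
        str_dt = h5py.string_dtype()
        h5.create_dataset("transcript_id", data=[k[0] for k in keys], dtype=str_dt)
        h5.create_dataset("position", data=[k[1] for k in keys])
        h5.create_dataset("read_id", data=[k[2] for k in keys], dtype=str_dt)
    return len(keys)


def load_features(path: str | Path) -> list[SiteReadFeatures]:
    with h5py.File(path, "r") as h5:
        raw = h5["raw"][:]
        err = h5["error"][:]
        label = h5["label"][:]
        tx = [s.decode() for s in h5["transcript_id"][:]]
        pos = h5["position"][:]
        rid = [s.decode() for s in h5["read_id"][:]]
    return [
        SiteReadFeatures(
            tx[i],
            int(pos[i]),
            rid[i],
            raw[i],
            err[i],
            None if label[i] < 0 else int(label[i]),
        )
        for i in range(len(tx))
    ]
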