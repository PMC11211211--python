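"""Read-to-site aggregation of methylation probabilities.

Two schemes turn the per-read probabilities pr_k of a site into the
transcriptome-level probability Pt:

* **multiple-instance pooling** (``mil``): the site is treated as a bag of
  reads and is methylated if at least one read is,

      Pt = 1 - prod_k (1 - pr_k),

  evaluated over a uniform random sample of exactly 20 reads drawn without
  replacement (sites with fewer than 20 reads are reported uncalled);

* **methylation frequency** (``frequency``):

      n_m = #{k : pr_k >= 0.5},   Pt = n_m / n,

  where the boundary value 0.5 counts as methylated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from m6aduet.model import ReadLevelPrediction

DEFAULT_SAMPLE_SIZE = 20
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class SitePrediction:
    """Transcriptome-level methylation call for one candidate site."""

    transcript_id: str
    position: int
    pt: float
    mode: str
    n_reads_used: int
    n_methylated: int | None = None  # frequency mode only

    def __post_init__(self) -> None:
        if not 0.0 <= self.pt <= 1.0:
            raise ValueError(f"pt = {self.pt} outside [0, 1]")
        if self.mode not in ("mil", "frequency"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if self.n_reads_used < 1:
            raise ValueError("n_reads_used must be positive")
        if self.mode == "frequency":
            if self.n_methylated is None:
                raise ValueError("frequency mode requires n_methylated")
            if self.pt != self.n_methylated / self.n_reads_used:
                raise ValueError("frequency mode requires pt = n_methylated / n_reads_used")


def _site_sampler(seed: int, transcript_id: str, position: int) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}\x1fmil\x1f{transcript_id}\x1f{position}".encode()).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:8], "little")))


def aggregate_mil(
    read_probs: Sequence[float],
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    rng: np.random.Generator | None = None,
    *,
    transcript_id: str = "",
    position: int = 0,
    seed: int = 0,
) -> SitePrediction | None:
    """Multiple-instance pooling over a seeded ``sample_size``-read sample.

    Returns ``None`` (site uncalled) when fewer than ``sample_size`` reads
    are available -- insufficient coverage is a reportable condition, not an
    exception.  The sample is uniform without replacement; the generator is
    derived from ``seed`` and the site key unless ``rng`` is supplied.
    """
    probs = np.asarray(read_probs, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("read probabilities must lie in [0, 1]")
    if probs.size < sample_size:
        return None
    if rng is None:
        rng = _site_sampler(seed, transcript_id, position)
    sample = probs[rng.choice(probs.size, size=sample_size, replace=False)]
    pt = float(1.0 - np.prod(1.0 - sample))
    return SitePrediction(transcript_id, position, pt, "mil", sample_size)


def aggregate_frequency(
    read_probs: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    transcript_id: str = "",
    position: int = 0,
) -> SitePrediction:
    """Thresholded methylation frequency; ``pr >= threshold`` counts as a
    methylated read (the boundary is methylated)."""
    probs = np.asarray(read_probs, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("aggregate_frequency requires at least one read")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("read probabilities must lie in [0, 1]")
    n_meth = int(np.sum(probs >= threshold))
    return SitePrediction(
        transcript_id, position, n_meth / probs.size, "frequency", int(probs.size), n_meth
    )


def aggregate_sites(
    read_preds: Iterable[ReadLevelPrediction],
    mode: str = "frequency",
    *,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> tuple[list[SitePrediction], list[tuple[str, int, int]]]:
    """Group read-level predictions by site and aggregate each group.

    Returns ``(called, uncalled)`` where ``uncalled`` lists
    ``(transcript_id, position, n_reads)`` for sites below the MIL coverage
    floor.  Site order follows first appearance in the input.
    """
    if mode not in ("mil", "frequency"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    groups: dict[tuple[str, int], list[float]] = {}
    for pred in read_preds:
        groups.setdefault((pred.transcript_id, pred.position), []).append(pred.pr)
    called: list[SitePrediction] = []
    uncalled: list[tuple[str, int, int]] = []
    for (tx, pos), probs in groups.items():
        if mode == "mil":
            sp = aggregate_mil(
                probs, sample_size, transcript_id=tx, position=pos, seed=seed
            )
            if sp is None:
                uncalled.append((tx, pos, len(probs)))
            else:
                called.append(sp)
        else:
            called.append(aggregate_frequency(probs, threshold, transcript_id=tx, position=pos))
    return called, uncalled


# ---------------------------------------------------------------------------
# TSV output


def write_read_predictions(path: str | Path, preds: Iterable[ReadLevelPrediction]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tread_id\tpr\n")
        for p in preds:
            fh.write(f"{p.transcript_id}\t{p.position}\t{p.read_id}\t{p.pr:.6f}\n")


def read_read_predictions(path: str | Path) -> list[ReadLevelPrediction]:
    preds = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["transcript_id", "position", "read_id", "pr"]:
            raise ValueError(f"{path}: bad read-prediction header")
        for line in fh:
            tx, pos, rid, pr = line.rstrip("\n").split("\t")
            preds.append(ReadLevelPrediction(tx, int(pos), rid, float(pr)))
    return preds


def write_site_predictions(
    path: str | Path,
    called: Iterable[SitePrediction],
    uncalled: Iterable[tuple[str, int, int]] = (),
    fivemers: Mapping[tuple[str, int], str] | None = None,
) -> None:
    """Site-level TSV: transcript_id, position, fivemer, n_reads_used,
    n_methylated (NA in MIL mode), pt, mode; uncalled sites carry pt = NA
    and mode ``uncalled_low_coverage``."""
    def motif(tx: str, pos: int) -> str:
        return fivemers.get((tx, pos), "NA") if fivemers else "NA"

    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tfivemer\tn_reads_used\tn_methylated\tpt\tmode\n")
        for sp in called:
            nm = "NA" if sp.n_methylated is None else str(sp.n_methylated)
            fh.write(
                f"{sp.transcript_id}\t{sp.position}\t{motif(sp.transcript_id, sp.position)}\t"
                f"{sp.n_reads_used}\t{nm}\t{sp.pt:.6f}\t{sp.mode}\n"
            )
        for tx, pos, n in uncalled:
            fh.write(f"{tx}\t{pos}\t{motif(tx, pos)}\t{n}\tNA\tNA\tuncalled_low_coverage\n")
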