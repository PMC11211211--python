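"""Synthetic DRS data with the statistical structure the method assumes.

The generator emulates what the upstream basecall/align/re-squiggle steps
would produce for a direct RNA run over random transcripts:

* **signal model** -- each 5-mer context has a mean current level drawn
  once from a seeded table (as real pore models are k-mer based), with
  i.i.d. Gaussian noise per sampled value; the number of values per base
  (the dwell) is shifted-geometric with support >= 1;
* **modification effect** -- at a methylated A the mean level of every
  position in the five overlapping windows covering it (i.e. positions
  A-2 .. A+2) is shifted by an additive delta, mimicking the
  multi-position signal disturbance that motivates 5-mer features;
* **error model** -- baseline mismatch/deletion/insertion rates and a
  Gaussian Phred quality, with rates multiplicatively inflated and quality
  depressed at the same methylated positions, so the raw-signal and
  basecalling-error views carry partially redundant, partially
  complementary evidence.

Modified sites occur only at motif positions; a per-read Bernoulli with
the site's stoichiometry decides whether each read is methylated there, so
read-level labels of 1 occur only at modified sites.  Candidate sites
closer than one 5-mer share a methylation cluster (one indicator per read)
so that overlapping windows never contradict each other's labels.

Everything is driven by a single seed; regenerating with the same config
is byte-identical on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from m6aduet.io import (
    BaseAlignmentRecord,
    CandidateSite,
    Event,
    EventAlignedRead,
    scan_motif_sites,
    write_alignment_table,
    write_event_table,
    write_fasta,
)

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give a cleanly separable dataset at
    desk scale (the ``default`` fixture)."""

    n_transcripts: int = 24
    transcript_length: int = 400
    coverage: int = 30  # full-length reads per transcript
    motif: str = "RRACH"
    site_mod_rate: float = 0.5  # per-cluster modification probability
    stoichiometry: float = 0.8  # per-read methylation probability at modified sites
    level_mean: float = 90.0  # k-mer table location (arbitrary current units)
    level_spread: float = 8.0  # k-mer table scale across 5-mers
    noise_sd: float = 2.5  # per-signal Gaussian noise
    delta: float = 4.0  # additive mean shift at methylated positions
    dwell_mean: float = 10.0  # mean signals per base (shifted geometric, >= 1)
    mismatch_rate: float = 0.03
    deletion_rate: float = 0.02
    insertion_rate: float = 0.02
    error_inflation: float = 4.0  # multiplicative rate inflation when methylated
    quality_mean: float = 32.0
    quality_sd: float = 4.0
    quality_depression: float = 10.0  # mean Phred drop when methylated
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_mod_rate", "stoichiometry", "mismatch_rate",
                     "deletion_rate", "insertion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.error_inflation < 0:
            raise ValueError("error_inflation must be >= 0")
        if self.n_transcripts < 1 or self.transcript_length < 5:
            raise ValueError("need at least one transcript of length >= 5")


@dataclass
class SimulatedDataset:
    """In-memory dataset plus truth; ``write`` emits the on-disk dialects."""

    cfg: SimConfig
    references: dict[str, str]
    reads: list[EventAlignedRead]
    alignments: list[BaseAlignmentRecord]
    sites: list[CandidateSite]
    site_truth: dict[tuple[str, int], dict] = field(default_factory=dict)
    read_labels: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write FASTA, the two TSV dialects and the truth tables; returns a
        manifest of sha256 checksums (also saved as manifest.json)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "references.fasta", self.references)
        write_event_table(outdir / "events.tsv", self.reads)
        write_alignment_table(outdir / "alignments.tsv", self.alignments)
        with open(outdir / "site_truth.tsv", "w") as fh:
            fh.write("transcript_id\tposition\tfivemer\tsite_modified\tstoichiometry\n")
            for site in self.sites:
                t = self.site_truth[(site.transcript_id, site.position)]
                fh.write(
                    f"{site.transcript_id}\t{site.position}\t{site.fivemer}\t"
                    f"{t['site_modified']}\t{t['stoichiometry']}\n"
                )
        with open(outdir / "read_labels.tsv", "w") as fh:
            fh.write("transcript_id\tposition\tread_id\tlabel\n")
            for (tx, pos, rid), lab in sorted(self.read_labels.items()):
                fh.write(f"{tx}\t{pos}\t{rid}\t{lab}\n")
        manifest = {}
        for name in ("references.fasta", "events.tsv", "alignments.tsv",
                     "site_truth.tsv", "read_labels.tsv"):
            manifest[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        (outdir / "manifest.json").write_text(
            json.dumps({"config": asdict(self.cfg), "sha256": manifest}, indent=2) + "\n"
        )
        return manifest


def _kmer_codes(seq: str) -> np.ndarray:
    """Code of the 5-mer centered on each position, over the sequence padded
    with A at the edges (edge levels only ever feed non-candidate bases)."""
    padded = "AA" + seq + "AA"
    idx = np.frompyfunc(BASES.index, 1, 1)(np.array(list(padded))).astype(np.int64)
    codes = np.zeros(len(seq), dtype=np.int64)
    for j in range(5):
        codes = codes * 4 + idx[j : j + len(seq)]
    return codes


def _clusters(positions: list[int], max_gap: int = 4) -> list[list[int]]:
    """Group candidate positions whose 5-mer windows overlap (gap <= 4 nt)."""
    clusters: list[list[int]] = []
    for pos in sorted(positions):
        if clusters and pos - clusters[-1][-1] <= max_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    return clusters


def simulate_dataset(cfg: SimConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Generate references, event-aligned reads, alignment records and truth.

    Raises a ``ValueError`` suggesting longer transcripts if the random
    references contain no motif site at all.  With ``outdir`` given, the
    dataset is also written to disk (see :meth:`SimulatedDataset.write`).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x73696D]))
    kmer_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6B6D65]))
    kmer_levels = kmer_rng.normal(cfg.level_mean, cfg.level_spread, 4**5)

    references: dict[str, str] = {}
    all_sites: list[CandidateSite] = []
    sites_by_tx: dict[str, list[CandidateSite]] = {}
    for t in range(cfg.n_transcripts):
        tx = f"tx{t:03d}"
        seq = "".join(rng.choice(list(BASES), size=cfg.transcript_length))
        references[tx] = seq
        sites = scan_motif_sites(tx, seq, cfg.motif)
        sites_by_tx[tx] = sites
        all_sites.extend(sites)
    if not all_sites:
        raise ValueError(
            "no motif sites in the simulated references; increase transcript_length "
            "or n_transcripts"
        )

    ds = SimulatedDataset(cfg, references, [], [], all_sites)
    geometric_p = 1.0 / cfg.dwell_mean
    mis = min(cfg.mismatch_rate * cfg.error_inflation, 0.45)
    dele = min(cfg.deletion_rate * cfg.error_inflation, 0.45)
    ins = min(cfg.insertion_rate * cfg.error_inflation, 1.0)

    for tx, seq in references.items():
        length = len(seq)
        codes = _kmer_codes(seq)
        base_levels = kmer_levels[codes]
        clusters = _clusters([s.position for s in sites_by_tx[tx]])
        modified = [bool(rng.random() < cfg.site_mod_rate) for _ in clusters]
        pos_to_cluster = {p: ci for ci, cl in enumerate(clusters) for p in cl}
        for site in sites_by_tx[tx]:
            ci = pos_to_cluster[site.position]
            ds.site_truth[(tx, site.position)] = {
                "site_modified": int(modified[ci]),
                "stoichiometry": cfg.stoichiometry if modified[ci] else 0.0,
            }

        for r in range(cfg.coverage):
            read_id = f"{tx}_read{r:04d}"
            # per-read methylation indicator, one per modified cluster
            meth_cluster = {
                ci: bool(modified[ci] and rng.random() < cfg.stoichiometry)
                for ci in range(len(clusters))
            }
            shifted = np.zeros(length, dtype=bool)
            for ci, cl in enumerate(clusters):
                if meth_cluster[ci]:
                    for p in cl:
                        shifted[max(0, p - 2) : min(length, p + 3)] = True
            for site in sites_by_tx[tx]:
                ci = pos_to_cluster[site.position]
                ds.read_labels[(tx, site.position, read_id)] = int(meth_cluster[ci])

            means = base_levels + cfg.delta * shifted
            n_sig = rng.geometric(geometric_p, size=length)
            noise = rng.normal(0.0, cfg.noise_sd, size=int(n_sig.sum()))
            values = np.repeat(means, n_sig) + noise
            bounds = np.concatenate([[0], np.cumsum(n_sig)])
            events = [
                Event(p, seq[p], tuple(values[bounds[p] : bounds[p + 1]].tolist()))
                for p in range(length)
            ]
            ds.reads.append(EventAlignedRead(read_id, tx, events))

            m_rate = np.where(shifted, mis, cfg.mismatch_rate)
            d_rate = np.where(shifted, dele, cfg.deletion_rate)
            i_rate = np.where(shifted, ins, cfg.insertion_rate)
            u = rng.random(length)
            is_del = u < d_rate
            is_mis = ~is_del & (u < d_rate + m_rate)
            ins_count = rng.poisson(i_rate)
            qual = np.clip(
                np.rint(rng.normal(
                    cfg.quality_mean - cfg.quality_depression * shifted,
                    cfg.quality_sd, size=length,
                )),
                1, 40,
            ).astype(int)
            for p in range(length):
                if is_del[p]:
                    status, q = "deletion", -1
                elif is_mis[p]:
                    status, q = "mismatch", int(qual[p])
                elif ins_count[p] > 0:
                    status, q = "insertion-adjacent", int(qual[p])
                else:
                    status, q = "match", int(qual[p])
                ds.alignments.append(
                    BaseAlignmentRecord(read_id, tx, p, seq[p], status, q, int(ins_count[p]))
                )

    if outdir is not None:
        ds.write(outdir)
    return ds


#: canned scenario names -> config overrides
FIXTURES = {
    "tiny": dict(n_transcripts=2, transcript_length=120, coverage=6),
    "default": dict(),
    # zero effect sizes; every site "modified" at stoichiometry 0.5 so labels
    # are i.i.d. coin flips independent of sequence context -- a permutation
    # null in which any AUC away from 0.5 indicates leakage
    "null": dict(delta=0.0, error_inflation=1.0, quality_depression=0.0,
                 site_mod_rate=1.0, stoichiometry=0.5),
}


def make_fixture(name: str, seed: int = 0) -> SimConfig:
    """Canned scenarios: ``tiny`` (sub-second, unit tests), ``default``
    (end-to-end training scale), ``null`` (zero effect sizes)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; valid: {sorted(FIXTURES)}")
    return replace(SimConfig(seed=seed), **FIXTURES[name])
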