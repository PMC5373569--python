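"""Synthetic inputs with full ground truth for every pipeline stage.

The generator emulates the study conditions the pipeline was built for:
four replicate small-RNA libraries from one condition, 15–30 nt inserts
with a 22-nt mode, a 3' sequencing adapter, correlated log-normal
expression across replicates, planted known-miRNA tags, planted genomic
hairpin precursors for novel discovery, rRNA/tRNA-like contaminant tags
(from a packaged synthetic decoy set), multi-species family matrices
evolved under a Dollo model on a known tree, and 3'UTRs with planted seed
sites.

Planted hairpins are built to satisfy the discovery criteria by
construction: a GC-balanced 21–23 nt mature forms the 5' arm, its reverse
complement (with 1–3 interior substitutions that open small bulges) the 3'
arm, joined by a homopolymeric-A apex loop so the duplex register is
unambiguous, with the canonical 2-nt 3' overhangs at both duplex ends.

All randomness flows from one seed through named spawned streams, so
adding a generator never perturbs earlier outputs and identical seeds give
byte-identical files.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord, ReferenceCatalog, revcomp, write_fasta, write_fastq
from . import dollo_phylo

_BASES = np.array(list("ACGT"))
#: substitutions guaranteed NOT to pair (Watson-Crick or GU wobble) with the
#: complement of the original base — used to open bulges in the star arm
_NONPAIRING = {"A": "CG", "C": "AC", "G": "AG", "T": "CT"}

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter


@dataclass
class SimulationConfig:
    seed: int = 0
    n_replicates: int = 4
    genome_length: int = 100_000
    n_planted_hairpins: int = 20
    n_known_mirnas: int = 50
    expression_mu: float = 5.0  # ln-scale mean of per-miRNA abundance
    expression_sigma: float = 1.2  # ln-scale spread across miRNAs
    replicate_sigma: float = 0.1  # ln-scale replicate-level noise
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    contaminant_fraction: float = 0.2
    length_mode: int = 22
    read_length: int = 50
    min_planted_count: int = 10  # floor for planted novel-hairpin tags
    no_insert_fraction: float = 0.02
    polya_fraction: float = 0.01
    lowq_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_replicates", "genome_length", "n_planted_hairpins", "n_known_mirnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG stream derived from the run seed."""
        offsets = {"genome": 1, "catalog": 2, "libraries": 3, "evolution": 4, "utrs": 5}
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(offsets[name],))
        )


@dataclass
class PlantedHairpin:
    name: str
    contig: str
    start: int  # precursor, 0-based half-open genomic
    end: int
    strand: str
    mature_arm: str  # always "5p" in this generator
    mature_seq: str
    star_seq: str
    precursor_seq: str
    mature_offset: int = 0  # mature start within the precursor


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream recovery checks."""

    hairpins: list[PlantedHairpin] = field(default_factory=list)
    known_names: list[str] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)
    true_counts: pd.DataFrame | None = None
    tree: object = None
    target_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "hairpins": [asdict(h) for h in self.hairpins],
            "known_names": self.known_names,
            "families": self.families,
            "true_counts": None
            if self.true_counts is None
            else self.true_counts.to_dict(orient="index"),
            "target_sites": [list(t) for t in self.target_sites],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _sample_mature(rng: np.random.Generator) -> str:
    """21-23 nt mature; GC-balanced stem, ends chosen so the planted duplex
    register cannot extend into the loop or the terminal overhang."""
    while True:
        L = int(rng.integers(21, 24))
        m = _random_seq(rng, L)
        first = "ACT"[rng.integers(0, 3)]  # not G: keeps the CC overhang unpaired
        tail = "".join("ACG"[i] for i in rng.integers(0, 3, 2))  # no T next to the A-loop
        m = first + m[1:-2] + tail
        core = m[:-2]
        gc = sum(b in "GC" for b in core)
        if gc >= math.ceil(0.45 * len(core)):
            return m


def build_precursor(mature: str, rng: np.random.Generator) -> tuple[str, str]:
    """Construct (precursor, star) around a mature placed on the 5' arm."""
    loop = "A" * int(rng.integers(8, 16))
    star_core = list(revcomp(mature[:-2]))
    n_mut = int(rng.integers(1, 4))
    positions = rng.choice(np.arange(2, len(star_core) - 3), size=n_mut, replace=False)
    for p in positions:
        choices = _NONPAIRING[star_core[p]]
        star_core[p] = choices[rng.integers(0, len(choices))]
    star = "".join(star_core) + "CC"
    return mature + loop + star, star


def _verified_hairpin(rng: np.random.Generator) -> tuple[str, str, str]:
    """Sample hairpins until the folder confirms the designed geometry.

    Rejection keeps only plants whose own MFE fold shows the mature on the
    5' arm with exact 2-nt 3' overhangs, small bulges and a stable stem —
    the discovery criteria a planted positive must satisfy by construction.
    """
    from .rnafold import fold, hairpin_metrics

    for _ in range(100):
        mature = _sample_mature(rng)
        prec, star = build_precursor(mature, rng)
        h = fold(prec)
        met = hairpin_metrics(h, (0, len(mature)))
        if (
            h.mfe_kcal_mol < -18.0
            and met.arm == "5p"
            and met.overhang_mature3 == 2
            and met.overhang_star3 == 2
            and met.max_bulge <= 8
        ):
            return mature, prec, star
    raise RuntimeError("could not construct a verified hairpin in 100 draws")


def make_genome(cfg: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Random background genome with non-overlapping planted hairpin loci."""
    rng = cfg.stream("genome")
    n = cfg.genome_length
    plants = []
    for k in range(cfg.n_planted_hairpins):
        mature, prec, star = _verified_hairpin(rng)
        plants.append((f"novel-sim-{k + 1}", mature, star, prec))
    footprint = sum(len(p[3]) for p in plants)
    if plants and n < 10 * footprint:
        raise ValueError(
            f"genome_length {n} < 10x planted footprint {footprint}"
        )
    genome = list(_random_seq(rng, n))
    margin = 150
    occupied: list[tuple[int, int]] = []
    truth = GroundTruth()
    for name, mature, star, prec in plants:
        for attempt in range(1000):
            start = int(rng.integers(margin, n - margin - len(prec)))
            end = start + len(prec)
            if all(end + 10 <= s or e + 10 <= start for s, e in occupied):
                break
        else:
            raise RuntimeError("cannot place hairpin without overlap after 1000 attempts")
        occupied.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genome[start:end] = list(prec if strand == "+" else revcomp(prec))
        truth.hairpins.append(
            PlantedHairpin(
                name=name,
                contig="chr1",
                start=start,
                end=end,
                strand=strand,
                mature_arm="5p",
                mature_seq=mature,
                star_seq=star,
                precursor_seq=prec,
                mature_offset=0,
            )
        )
    return [SequenceRecord(id="chr1", seq="".join(genome))], truth


def make_known_catalog(cfg: SimulationConfig, species: str = "dre") -> tuple[ReferenceCatalog, dict[str, str]]:
    """Random known-miRNA catalog with hairpin precursors and family labels.

    Families group consecutive matures in blocks of 1-5 members whose
    precursors differ by at most one substitution from the family seed, so
    the >98%-identity / <2-mismatch family rule is satisfiable by design.
    """
    rng = cfg.stream("catalog")
    matures, precursors, links = [], [], []
    families: dict[str, str] = {}
    link_map: dict[str, list[str]] = {}
    i = 0
    fam_idx = 0
    while i < cfg.n_known_mirnas:
        fam_idx += 1
        fam_size = int(rng.integers(1, 6))
        fam_size = min(fam_size, cfg.n_known_mirnas - i)
        seed_mature = _sample_mature(rng)
        seed_prec, _ = build_precursor(seed_mature, rng)
        fam_name = f"sim-fam-{fam_idx}"
        for member in range(fam_size):
            i += 1
            mid = f"{species}-sim-miR-{i:03d}"
            pid = f"{species}-sim-mir-{i:03d}"
            mature = list(seed_mature)
            prec = list(seed_prec)
            if member > 0:
                # one substitution mid-mature, mirrored in the precursor:
                # members stay within 1 mismatch of the family seed precursor
                p = 8 + int(rng.integers(0, 6))
                mature[p] = _NONPAIRING[mature[p]][0]
                prec[p] = mature[p]
            matures.append(SequenceRecord(id=mid, seq="".join(mature)))
            precursors.append(SequenceRecord(id=pid, seq="".join(prec)))
            link_map[mid] = [pid]
            families[mid] = fam_name
    catalog = ReferenceCatalog(
        species=species, matures=matures, precursors=precursors, links=link_map
    )
    return catalog, families


def load_decoys() -> dict[str, list[SequenceRecord]]:
    """Packaged synthetic contaminant set, grouped by class."""
    from .io_formats import read_fasta
    from Bio import SeqIO

    path = importlib.resources.files("mirseed.data").joinpath("decoys_synthetic.fa")
    grouped: dict[str, list[SequenceRecord]] = {}
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            cls = dict(
                kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
            ).get("class", "other")
            grouped.setdefault(cls, []).append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    return grouped


def _insert_length(rng: np.random.Generator, mode: int) -> int:
    """Discrete triangular length in [15, 30] peaked at ``mode``."""
    lengths = np.arange(15, 31)
    weights = 1.0 / (1.0 + np.abs(lengths - mode)) ** 2
    return int(rng.choice(lengths, p=weights / weights.sum()))


def simulate_libraries(
    cfg: SimulationConfig,
    truth: GroundTruth,
    known_catalog: ReferenceCatalog,
    outdir: str | Path | None = None,
) -> list[list[SequenceRecord]]:
    """Replicate read sets (optionally written as rep{i}.fastq.gz).

    Per-miRNA abundance is log-normal across miRNAs with multiplicative
    replicate noise, so log-counts correlate across replicates at
    sigma^2 / (sigma^2 + sigma_rep^2).  Planted novel-hairpin tags are
    floored at ``min_planted_count`` reads per replicate so discovery's
    read-support criterion is meaningful.  Contaminants are decoy
    fragments; small fractions of adapter-only, poly-A and low-quality
    reads exercise the cleaning stage.
    """
    if not known_catalog.matures:
        raise ValueError("known catalog is empty")
    rng = cfg.stream("libraries")
    decoys = load_decoys()
    decoy_pool = [r for group in decoys.values() for r in group]

    mirnas = [(m.id, m.seq, False) for m in known_catalog.matures]
    mirnas += [(h.name, h.mature_seq, True) for h in truth.hairpins]
    truth.known_names = [m.id for m in known_catalog.matures]

    lam = np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma, len(mirnas)))
    counts = np.zeros((len(mirnas), cfg.n_replicates), dtype=int)
    for r in range(cfg.n_replicates):
        noise = np.exp(rng.normal(0.0, cfg.replicate_sigma, len(mirnas)))
        counts[:, r] = np.maximum(np.rint(lam * noise), 0).astype(int)
    for i, (_, _, planted) in enumerate(mirnas):
        if planted:
            counts[i] = np.maximum(counts[i], cfg.min_planted_count)

    libraries: list[list[SequenceRecord]] = []
    for r in range(cfg.n_replicates):
        reads: list[tuple[str, str]] = []  # (insert-or-raw flag handled below)
        raw: list[SequenceRecord] = []

        def emit(insert: str, qual_val: int = 40) -> None:
            seq = (insert + cfg.adapter)[: cfg.read_length]
            if len(seq) < cfg.read_length:
                seq = seq + _random_seq(rng, cfg.read_length - len(seq))
            if cfg.error_rate > 0:
                arr = list(seq)
                hits = np.nonzero(rng.random(len(arr)) < cfg.error_rate)[0]
                for p in hits:
                    arr[p] = "ACGT"[(("ACGT".index(arr[p])) + int(rng.integers(1, 4))) % 4]
                seq = "".join(arr)
            raw.append(
                SequenceRecord(
                    id=f"rep{r + 1}_read{len(raw) + 1}",
                    seq=seq,
                    qual=[qual_val] * cfg.read_length,
                )
            )

        for i, (_, seq, _) in enumerate(mirnas):
            for _ in range(counts[i, r]):
                emit(seq)
        n_mirna_reads = int(counts[:, r].sum())
        cf = cfg.contaminant_fraction
        n_contam = int(round(n_mirna_reads * cf / (1 - cf))) if cf > 0 else 0
        for _ in range(n_contam):
            decoy = decoy_pool[rng.integers(0, len(decoy_pool))]
            L = min(_insert_length(rng, cfg.length_mode), len(decoy.seq))
            start = int(rng.integers(0, len(decoy.seq) - L + 1))
            emit(decoy.seq[start : start + L])
        n_total = n_mirna_reads + n_contam
        for _ in range(int(round(n_total * cfg.no_insert_fraction))):
            emit("")
        for _ in range(int(round(n_total * cfg.polya_fraction))):
            emit("A" * _insert_length(rng, cfg.length_mode))
        for _ in range(int(round(n_total * cfg.lowq_fraction))):
            emit(_random_seq(rng, _insert_length(rng, cfg.length_mode)), qual_val=5)
        order = rng.permutation(len(raw))
        raw = [raw[k] for k in order]
        for k, rec in enumerate(raw):
            rec.id = f"rep{r + 1}_read{k + 1}"
        libraries.append(raw)

    truth.true_counts = pd.DataFrame(
        counts,
        index=[name for name, _, _ in mirnas],
        columns=[f"rep{r + 1}" for r in range(cfg.n_replicates)],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r, lib in enumerate(libraries):
            write_fastq(lib, outdir / f"rep{r + 1}.fastq.gz")
    return libraries


def simulate_family_evolution(
    tree,
    n_families: int,
    loss_prob: float,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, object]:
    """Binary family matrix evolved under Dollo gain/loss on a known tree.

    Each family is gained at one uniformly chosen node (internal or leaf)
    and lost independently with ``loss_prob`` on every branch below the
    gain; a leaf carries the family iff no loss occurred on its path.
    """
    if not 0 <= loss_prob < 0.5:
        raise ValueError("loss_prob must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = tree.root if isinstance(tree, dollo_phylo.PhyloTree) else tree
    nodes = list(dollo_phylo.iter_nodes(root))
    leaves = sorted(dollo_phylo.leaf_set(root))
    columns = {}
    for f in range(n_families):
        gain = nodes[rng.integers(0, len(nodes))]
        present: dict[str, int] = {}

        def walk(node, on: bool) -> None:
            if isinstance(node, tuple):
                for child in node:
                    walk(child, on and rng.random() >= loss_prob)
            else:
                present[node] = 1 if on else 0

        walk(gain, True)
        columns[f"fam{f + 1}"] = [present.get(l, 0) for l in leaves]
    matrix = pd.DataFrame(columns, index=leaves)
    return matrix, dollo_phylo.PhyloTree(root)


def make_utrs(
    n_utrs: int,
    mirnas: dict[str, str],
    seed: int | np.random.Generator = 0,
    utr_length: int = 400,
) -> tuple[list[SequenceRecord], list[tuple[str, int, str]]]:
    """3'UTRs with one planted perfect 7mer-m8 seed site each.

    The planted site is the reverse complement of miRNA positions 2-8; the
    base facing miRNA position 1 is forced to ``C`` so the site classifies
    as 7mer-m8 (not 8mer/7mer-A1).  Returns (records, sites) with sites as
    (utr_id, 0-based site start, mirna_id).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = sorted(mirnas)
    records, sites = [], []
    for k in range(n_utrs):
        uid = f"utr{k + 1}"
        seq = list(_random_seq(rng, utr_length))
        if names:
            mirna = names[k % len(names)]
            seed7 = mirnas[mirna][1:8]
            site = revcomp(seed7)
            pos = int(rng.integers(30, utr_length - 40))
            seq[pos : pos + 7] = list(site)
            seq[pos + 7] = "C"
            sites.append((uid, pos, mirna))
        records.append(SequenceRecord(id=uid, seq="".join(seq)))
    return records, sites
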