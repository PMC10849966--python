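"""Ground-truth simulator for ancient mitochondrial DNA experiments.

Generates every input the analysis chain consumes — a circular reference,
aligned damaged fragments with a complete truth table, PCR duplicates,
lineage-variant genomes with a diagnostic-position table, and strict-clock
sequence alignments with dated tips — so each downstream stage can be
tested against known ground truth.

The fragment model follows the single-stranded-library signature: cytosine
deamination (C→T in read orientation) concentrated at both fragment ends
and decaying geometrically into the molecule, on top of uniform sequencing
error.  Present-day contaminant fragments derive from a distinct genome and
carry sequencing error only — no deamination.  Fragment lengths are
lognormal (median 55 bp, sigma 0.35 on the log scale, clamped), a typical
ancient-DNA distribution.  Default terminal deamination rates (0.40 at the
5' end, 0.35 at the 3' end) sit mid-range for well-preserved Pleistocene
single-stranded libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import C, N, T, complement, decode, encode, revcomp
from .alignment import CIRCULAR_COMMENT, AlignedFragment


@dataclass
class ReferenceGenome:
    """A (by default circular) reference sequence over {A,C,G,T}."""

    name: str
    sequence: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def encoded(self) -> np.ndarray:
        return encode(self.sequence)


def geometric_decay(delta0: float, lam: float = 0.5, window: int = 15) -> np.ndarray:
    """Per-position damage probabilities delta0 * lam**i for i in 0..window-1."""
    return delta0 * lam ** np.arange(window, dtype=float)


@dataclass
class DamageModel:
    """Terminal C→T deamination plus uniform sequencing error.

    ``delta5[i]`` / ``delta3[i]`` give the C→T probability at read position
    i from the 5' / 3' end, in read orientation; damage applies only where
    the template base (read orientation) is C.  ``error_rate`` is the
    per-base probability of a uniform substitution to one of the other
    three bases.
    """

    delta5: np.ndarray = field(default_factory=lambda: geometric_decay(0.40))
    delta3: np.ndarray = field(default_factory=lambda: geometric_decay(0.35))
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        self.delta5 = np.asarray(self.delta5, dtype=float)
        self.delta3 = np.asarray(self.delta3, dtype=float)
        for arr in (self.delta5, self.delta3):
            if arr.ndim != 1 or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("damage probabilities must be 1-d in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    @classmethod
    def none(cls) -> "DamageModel":
        return cls(delta5=np.zeros(15), delta3=np.zeros(15), error_rate=0.0)


@dataclass
class LibraryConfig:
    """Sequencing-library simulation parameters.

    Lengths are lognormal: exp(Normal(log(length_mean), length_sd)),
    rounded and clamped to [length_min, length_max].  ``mapq_choices`` /
    ``mapq_weights`` give the sampling distribution of mapping qualities
    (most fragments map confidently; a minority fall below the MQ 25
    filter).
    """

    n_fragments: int = 1000
    length_mean: float = 55.0
    length_sd: float = 0.35
    length_min: int = 20
    length_max: int = 150
    contamination_fraction: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0
    mapq_choices: tuple[int, ...] = (0, 20, 25, 30, 37, 60)
    mapq_weights: tuple[float, ...] = (0.02, 0.03, 0.05, 0.10, 0.20, 0.60)

    def __post_init__(self) -> None:
        if self.length_min < 20:
            raise ValueError("length_min must be >= 20")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    fragment_id: str
    origin: str  # 'endogenous' | 'contaminant'
    damage_positions: list[int]  # read coordinates where C→T was injected
    duplicate_set: str
    source_genome: str
    pre_error_read: str = ""  # read orientation, post-damage pre-error (not serialised)


@dataclass
class TruthTable:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.fragment_id in self.records:
            raise ValueError(f"duplicate truth record {rec.fragment_id}")
        self.records[rec.fragment_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, fragment_id: str) -> TruthRecord:
        return self.records[fragment_id]

    def n_contaminant(self) -> int:
        return sum(r.origin == "contaminant" for r in self.records.values())

    def duplicate_sets(self) -> dict[str, list[str]]:
        sets: dict[str, list[str]] = {}
        for r in self.records.values():
            sets.setdefault(r.duplicate_set, []).append(r.fragment_id)
        return sets

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fragment_id": list(self.records),
                "origin": [r.origin for r in self.records.values()],
                "duplicate_set": [r.duplicate_set for r in self.records.values()],
                "source_genome": [r.source_genome for r in self.records.values()],
                "damage_positions": [
                    ",".join(map(str, r.damage_positions))
                    for r in self.records.values()
                ],
            }
        )


def simulate_reference(length: int, gc: float = 0.44, seed: int = 0) -> ReferenceGenome:
    """Random circular reference of exact ``length`` with target GC content."""
    if length < 1000:
        raise ValueError("simulated reference length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return ReferenceGenome(name="sim_ref", sequence=decode(codes), circular=True)


def make_contaminant(
    ref: ReferenceGenome, n_substitutions: int = 20, seed: int = 0
) -> ReferenceGenome:
    """Present-day contaminant source: the reference plus fixed substitutions."""
    rng = np.random.default_rng(seed)
    codes = ref.encoded.copy()
    sites = rng.choice(len(codes), size=n_substitutions, replace=False)
    codes[sites] = (codes[sites] + rng.integers(1, 4, size=n_substitutions)) % 4
    return ReferenceGenome(
        name=f"{ref.name}_contaminant", sequence=decode(codes), circular=ref.circular
    )


def _apply_error(read: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return read
    hit = rng.random(len(read)) < error_rate
    n = int(hit.sum())
    if n:
        read = read.copy()
        read[hit] = (read[hit] + rng.integers(1, 4, size=n)) % 4
    return read


def _build_fragment(
    frag_id: str,
    start: int,
    length: int,
    strand: str,
    mapq: int,
    read: np.ndarray,
    ref_length: int,
) -> AlignedFragment:
    idx = (start + np.arange(length)) % ref_length
    if strand == "+":
        obs_base = read
        obs_read = np.arange(length)
    else:
        obs_base = complement(read)[::-1]
        obs_read = np.arange(length - 1, -1, -1)
    return AlignedFragment(
        id=frag_id,
        ref_start=start,
        strand=strand,
        mapq=mapq,
        read_length=length,
        obs_ref_pos=idx,
        obs_read_pos=obs_read,
        obs_base=obs_base,
        ref_span=length,
        read_seq=decode(read),
    )


def simulate_fragments(
    ref: ReferenceGenome,
    damage: DamageModel,
    lib: LibraryConfig,
    contaminant: ReferenceGenome | None = None,
) -> tuple[list[AlignedFragment], TruthTable]:
    """Simulate aligned fragments with a complete per-fragment truth table.

    Fragments are placed uniformly on the circle (wrapping allowed) on
    random strands.  Endogenous fragments receive terminal C→T deamination
    in read orientation (5' then 3' channel, combined per position as
    1-(1-d5)(1-d3)), then uniform sequencing error; contaminant fragments
    (Binomial(n, contamination_fraction) of them) receive error only.
    Duplicates are added separately via :func:`inject_duplicates`.
    """
    if len(ref) == 0:
        raise ValueError("empty reference")
    rng = np.random.default_rng(lib.seed)
    L = len(ref)
    ref_codes = ref.encoded
    if contaminant is None and lib.contamination_fraction > 0:
        contaminant = make_contaminant(ref, seed=lib.seed + 1)
    cont_codes = contaminant.encoded if contaminant is not None else None

    n = lib.n_fragments
    is_cont = rng.random(n) < lib.contamination_fraction
    lengths = np.clip(
        np.rint(rng.lognormal(np.log(lib.length_mean), lib.length_sd, size=n)),
        lib.length_min,
        lib.length_max,
    ).astype(int)
    starts = rng.integers(0, L, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    mapqs = rng.choice(
        lib.mapq_choices, size=n, p=np.asarray(lib.mapq_weights) / sum(lib.mapq_weights)
    )

    w5, w3 = len(damage.delta5), len(damage.delta3)
    fragments: list[AlignedFragment] = []
    truth = TruthTable()
    for i in range(n):
        length = int(lengths[i])
        start = int(starts[i])
        strand = str(strands[i])
        src = cont_codes if is_cont[i] else ref_codes
        src_name = contaminant.name if is_cont[i] else ref.name
        idx = (start + np.arange(length)) % L
        template = src[idx]
        read = complement(template)[::-1] if strand == "-" else template.copy()

        damage_positions: list[int] = []
        if not is_cont[i]:
            p = np.zeros(length)
            k5 = min(w5, length)
            p[:k5] = damage.delta5[:k5]
            k3 = min(w3, length)
            p3 = np.zeros(length)
            p3[length - k3 :] = damage.delta3[:k3][::-1]
            p = 1.0 - (1.0 - p) * (1.0 - p3)
            hit = (read == C) & (rng.random(length) < p)
            if hit.any():
                read = read.copy()
                read[hit] = T
                damage_positions = np.nonzero(hit)[0].tolist()
        pre_error = decode(read)
        read = _apply_error(read, damage.error_rate, rng)

        frag_id = f"frag{i:06d}"
        fragments.append(
            _build_fragment(frag_id, start, length, strand, int(mapqs[i]), read, L)
        )
        truth.add(
            TruthRecord(
                fragment_id=frag_id,
                origin="contaminant" if is_cont[i] else "endogenous",
                damage_positions=damage_positions,
                duplicate_set=frag_id,
                source_genome=src_name,
                pre_error_read=pre_error,
            )
        )
    return fragments, truth


def replicate_fragment(
    frag: AlignedFragment,
    truth_record: TruthRecord,
    error_rate: float,
    rng: np.random.Generator,
    copy_id: str,
) -> tuple[AlignedFragment, TruthRecord]:
    """One PCR copy of ``frag``: same coordinates/strand, fresh sequencing error."""
    read = _apply_error(encode(truth_record.pre_error_read), error_rate, rng)
    copy = AlignedFragment(
        id=copy_id,
        ref_start=frag.ref_start,
        strand=frag.strand,
        mapq=frag.mapq,
        read_length=frag.read_length,
        obs_ref_pos=frag.obs_ref_pos.copy(),
        obs_read_pos=frag.obs_read_pos.copy(),
        obs_base=read if frag.strand == "+" else complement(read)[::-1],
        ref_span=frag.ref_span,
        read_seq=decode(read),
    )
    rec = TruthRecord(
        fragment_id=copy_id,
        origin=truth_record.origin,
        damage_positions=list(truth_record.damage_positions),
        duplicate_set=truth_record.duplicate_set,
        source_genome=truth_record.source_genome,
        pre_error_read=truth_record.pre_error_read,
    )
    return copy, rec


def inject_duplicates(
    fragments: list[AlignedFragment],
    truth: TruthTable,
    duplicate_rate: float,
    seed: int = 0,
    error_rate: float = 0.001,
) -> tuple[list[AlignedFragment], TruthTable]:
    """Add one PCR copy per fragment with probability ``duplicate_rate``.

    Copies share start, end and strand with their originals and receive
    independent sequencing error applied to the pre-error (post-damage)
    read.  Truth duplicate sets are updated in place semantics-wise but a
    new list / table is returned.
    """
    if not 0 <= duplicate_rate < 1:
        raise ValueError("duplicate_rate must be in [0, 1)")
    if duplicate_rate == 0:
        return fragments, truth
    rng = np.random.default_rng(seed)
    out = list(fragments)
    new_truth = TruthTable(dict(truth.records))
    for frag in fragments:
        if rng.random() < duplicate_rate:
            copy_id = f"{frag.id}_dup1"
            copy, rec = replicate_fragment(
                frag, truth[frag.id], error_rate, rng, copy_id
            )
            out.append(copy)
            new_truth.add(rec)
    return out, new_truth


# ---------------------------------------------------------------------------
# Lineage-variant genomes + diagnostic table (substrate for taxonomy tests)
# ---------------------------------------------------------------------------

def simulate_lineage_genomes(
    ref: ReferenceGenome, n_sites: int = 60, seed: int = 0
) -> tuple[dict[str, ReferenceGenome], pd.DataFrame]:
    """Create sapiens/neanderthal/denisovan genome variants plus the matching
    diagnostic-position table.

    The reference plays the H. sapiens state; the two archaic genomes carry
    distinct substitutions at ``n_sites`` random positions each (with some
    sites shared between the archaics, mimicking their common ancestry).
    Returns ({lineage: genome}, diagnostic table DataFrame with 1-based
    positions and per-lineage base columns).
    """
    rng = np.random.default_rng(seed)
    codes = ref.encoded
    L = len(codes)
    sites = np.sort(rng.choice(L, size=n_sites, replace=False))
    sap = codes.copy()
    nea = codes.copy()
    den = codes.copy()
    rows = []
    for s in sites:
        kind = rng.random()
        shift = int(rng.integers(1, 4))
        alt = (codes[s] + shift) % 4
        if kind < 0.4:  # sapiens vs both archaics
            nea[s] = alt
            den[s] = alt
        elif kind < 0.7:  # neanderthal-specific
            nea[s] = alt
        else:  # denisovan-specific
            den[s] = alt
        rows.append(
            {
                "position": int(s) + 1,
                "base_sapiens": decode(sap[s : s + 1]),
                "base_neanderthal": decode(nea[s : s + 1]),
                "base_denisovan": decode(den[s : s + 1]),
            }
        )
    genomes = {
        "sapiens": ReferenceGenome("sapiens_state", decode(sap), ref.circular),
        "neanderthal": ReferenceGenome("neanderthal_state", decode(nea), ref.circular),
        "denisovan": ReferenceGenome("denisovan_state", decode(den), ref.circular),
    }
    return genomes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Strict-clock sequence evolution with dated tips
# ---------------------------------------------------------------------------

@dataclass
class ClockSimConfig:
    """Strict-clock Jukes-Cantor simulation over a time-calibrated tree.

    ``tree`` is a rooted dendropy tree (or newick string) with branch
    lengths in years; ``tip_dates`` map taxon labels to years before
    present.  The tree must be ultrametric in time: root age =
    tip_date + root-to-tip path length, identical for every tip.
    """

    tree: dendropy.Tree | str
    rate: float  # substitutions / site / year
    seq_length: int
    tip_dates: dict[str, float]
    seed: int = 0

    def resolved_tree(self) -> dendropy.Tree:
        if isinstance(self.tree, dendropy.Tree):
            return self.tree
        return dendropy.Tree.get(data=self.tree, schema="newick")


def _check_ultrametric(tree: dendropy.Tree, tip_dates: dict[str, float]) -> float:
    """Return the implied root age; raise if tip depths and dates disagree."""
    root_ages = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in tip_dates:
            raise ValueError(f"tip {label!r} has no date")
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        root_ages.append(depth + tip_dates[label])
    root_ages = np.asarray(root_ages)
    if np.ptp(root_ages) > 1e-6 * max(1.0, root_ages.max()):
        raise ValueError(
            "tree is not ultrametric in time: root ages implied by tips "
            f"range over [{root_ages.min():.3f}, {root_ages.max():.3f}]"
        )
    return float(root_ages.mean())


def simulate_clock_alignment(
    cfg: ClockSimConfig,
) -> tuple[dict[str, str], dict[str, float]]:
    """Evolve sequences down the tree under Jukes-Cantor at a strict clock.

    Along a branch of duration t years, each site substitutes with
    probability (3/4)(1 - exp(-(4/3) * rate * t)), to a uniformly chosen
    different base — the exact JC transition probability.
    """
    if cfg.rate < 0:
        raise ValueError("rate must be >= 0")
    tree = cfg.resolved_tree()
    _check_ultrametric(tree, cfg.tip_dates)
    rng = np.random.default_rng(cfg.seed)
    root_seq = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    alignment: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * cfg.rate * t))
            hit = rng.random(cfg.seq_length) < p_change
            seq = parent_seq.copy()
            nhit = int(hit.sum())
            if nhit:
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=nhit)) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            alignment[node.taxon.label] = decode(seq)
    return alignment, dict(cfg.tip_dates)


def _random_coalescence(
    tips: dict[str, float],
    taxa: dendropy.TaxonNamespace,
    rng: np.random.Generator,
    scale: float,
) -> tuple[dendropy.Node, float]:
    """Merge dated lineages pairwise at random; each merge happens at
    max(child ages) + Exponential(scale) years.  Returns (root node, age)."""
    nodes: list[tuple[dendropy.Node, float]] = [
        (dendropy.Node(taxon=taxa.get_taxon(label)), float(tips[label]))
        for label in sorted(tips)
    ]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        (a, age_a), (b, age_b) = nodes[i], nodes[j]
        merge_age = max(age_a, age_b) + float(rng.exponential(scale))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = merge_age - age_a
        b.edge.length = merge_age - age_b
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (int(i), int(j))]
        nodes.append((parent, merge_age))
    return nodes[0]


def random_serial_tree(
    tip_dates: dict[str, float],
    seed: int = 0,
    coalescent_scale: float = 5000.0,
    outgroup: Sequence[str] = (),
) -> dendropy.Tree:
    """Random time-calibrated tree over serially sampled (dated) tips.

    Branch lengths are in years; the tree is ultrametric in time by
    construction.  If ``outgroup`` tips are given they are coalesced
    separately and joined to the ingroup at the root, guaranteeing outgroup
    monophyly (the substrate outgroup rooting assumes).
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(sorted(tip_dates))
    og = set(outgroup)
    unknown = og - set(tip_dates)
    if unknown:
        raise ValueError(f"outgroup tip(s) without dates: {sorted(unknown)}")
    ingroup_tips = {k: v for k, v in tip_dates.items() if k not in og}
    if og:
        in_node, in_age = _random_coalescence(ingroup_tips, taxa, rng, coalescent_scale)
        og_tips = {k: tip_dates[k] for k in og}
        if len(og_tips) == 1:
            label = next(iter(og_tips))
            out_node = dendropy.Node(taxon=taxa.get_taxon(label))
            out_age = float(og_tips[label])
        else:
            out_node, out_age = _random_coalescence(og_tips, taxa, rng, coalescent_scale)
        root_age = max(in_age, out_age) + float(rng.exponential(coalescent_scale))
        root = dendropy.Node()
        root.add_child(in_node)
        root.add_child(out_node)
        in_node.edge.length = root_age - in_age
        out_node.edge.length = root_age - out_age
    else:
        root, _ = _random_coalescence(ingroup_tips, taxa, rng, coalescent_scale)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sam(fragments: list[AlignedFragment], ref: ReferenceGenome, path) -> None:
    """Write simulated fragments as SAM against ``ref``.

    Fragments spanning the circular origin are emitted as a single record
    whose alignment extends past the @SQ length; the circular convention is
    declared in a @CO header line and undone by
    :func:`paleomito.alignment.read_sam`.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": ref.name, "LN": len(ref)}],
            "CO": [CIRCULAR_COMMENT],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for frag in fragments:
            if frag.read_seq is None:
                raise ValueError(f"fragment {frag.id} has no read sequence to emit")
            rec = pysam.AlignedSegment(header)
            rec.query_name = frag.id
            rec.flag = 16 if frag.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = frag.ref_start
            rec.mapping_quality = frag.mapq
            rec.cigarstring = f"{frag.read_length}M"
            seq = frag.read_seq
            if frag.strand == "-":
                seq = decode(revcomp(encode(seq)))
            rec.query_sequence = seq
            fh.write(rec)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: TruthTable, path) -> None:
    truth.to_dataframe().to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"damage_positions": str}, keep_default_na=False)
    table = TruthTable()
    for row in df.itertuples(index=False):
        dmg = [int(x) for x in str(row.damage_positions).split(",") if x not in ("", "nan")]
        table.add(
            TruthRecord(
                fragment_id=row.fragment_id,
                origin=row.origin,
                damage_positions=dmg,
                duplicate_set=row.duplicate_set,
                source_genome=row.source_genome,
            )
        )
    return table
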