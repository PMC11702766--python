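"""CRISPRi guide libraries and dual-guide barcoded construct layouts.

A screen library is a set of CRISPRi guides, each a 20-nt protospacer
targeting one gene, plus a handful of negative-control guides directed at
the inert *HO* endonuclease locus.  Dual-guide constructs carry an unordered
pair of distinct guides together with two random barcodes expressed from
divergent reporters: a 22-nt barcode on the UBC6 (normalizer) side and a
23-nt barcode on the PCL5 (stress-reporter) side.  A genetic perturbation is
identified with its unordered guide pair; several independently barcoded
constructs may carry the same perturbation, which is what makes barcode-level
replication (and the >=2-barcode filter downstream) possible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

CONTROL_GENE = "HO"
PROTOSPACER_LEN = 20
BARCODE_LEN_UBC6 = 22
BARCODE_LEN_PCL5 = 23


class ParameterError(ValueError):
    """Invalid library or simulation parameters."""


def random_dna(rng: np.random.Generator, length: int, n: int = 1) -> list[str]:
    """Draw ``n`` uniform random DNA strings of the given length."""
    idx = rng.integers(0, 4, size=(n, length))
    arr = DNA_ALPHABET[idx]
    return [bytes(row).decode("ascii") for row in arr]


def gc_fraction(seq: str) -> float:
    """Exact G+C fraction of a DNA string."""
    if not seq:
        raise ParameterError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class Guide:
    """One CRISPRi guide: a 20-nt protospacer aimed at a single gene."""

    guide_id: str
    gene: str
    protospacer: str
    gc_fraction: float
    is_negative_control: bool = False

    def __post_init__(self):
        if set(self.protospacer) - set("ACGT"):
            raise ParameterError(f"protospacer has non-ACGT characters: {self.protospacer}")


@dataclass
class GuideLibrary:
    """A guide set with fast lookup by id and by protospacer."""

    guides: list[Guide]
    _by_id: dict = field(default_factory=dict, repr=False)
    _proto_to_id: dict = field(default_factory=dict, repr=False)
    _proto_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self._by_id = {g.guide_id: g for g in self.guides}
        self._proto_to_id = {g.protospacer: g.guide_id for g in self.guides}
        if len(self._by_id) != len(self.guides):
            raise ParameterError("duplicate guide_id in library")

    def __len__(self) -> int:
        return len(self.guides)

    def __getitem__(self, guide_id: str) -> Guide:
        return self._by_id[guide_id]

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def controls(self) -> list[Guide]:
        return [g for g in self.guides if g.is_negative_control]

    @property
    def control_ids(self) -> list[str]:
        return [g.guide_id for g in self.controls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "gene": [g.gene for g in self.guides],
                "protospacer": [g.protospacer for g in self.guides],
                "gc_fraction": [g.gc_fraction for g in self.guides],
                "is_negative_control": [g.is_negative_control for g in self.guides],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GuideLibrary":
        guides = [
            Guide(
                guide_id=str(r.guide_id),
                gene=str(r.gene),
                protospacer=str(r.protospacer),
                gc_fraction=float(r.gc_fraction),
                is_negative_control=bool(r.is_negative_control),
            )
            for r in df.itertuples()
        ]
        return cls(guides)

    def _protospacer_matrix(self) -> np.ndarray:
        if self._proto_matrix is None:
            self._proto_matrix = np.frombuffer(
                "".join(g.protospacer for g in self.guides).encode("ascii"), dtype=np.uint8
            ).reshape(len(self.guides), PROTOSPACER_LEN)
        return self._proto_matrix

    def match_protospacer(self, seq: str, max_mismatch: int = 0) -> str | None:
        """Match a 20-mer to a unique guide within ``max_mismatch`` substitutions.

        Returns the guide_id, or None if no guide matches, or raises
        :class:`AmbiguousMatch` if two or more guides tie at the minimal
        (allowed) distance.
        """
        if len(seq) != PROTOSPACER_LEN:
            return None
        hit = self._proto_to_id.get(seq)
        if hit is not None:
            return hit
        if max_mismatch == 0:
            return None
        q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        dists = (self._protospacer_matrix() != q).sum(axis=1)
        best = dists.min()
        if best > max_mismatch:
            return None
        winners = np.flatnonzero(dists == best)
        if len(winners) > 1:
            raise AmbiguousMatch(seq)
        return self.guides[int(winners[0])].guide_id


class AmbiguousMatch(Exception):
    """A query sequence matched two or more guides equally well."""


def generate_guide_library(
    n_guides: int, n_controls: int, n_genes: int, seed: int | np.random.Generator
) -> GuideLibrary:
    """Generate a synthetic guide library.

    ``n_genes`` counts distinct target genes including HO (the negative
    control target) as one gene whenever controls are present.  Non-control
    guides are spread over the remaining genes so that every gene receives at
    least one guide and some genes receive several, as in a real library.
    Per-guide GC content is drawn with a wide spread so a realistic minority
    of guides falls below the 25% GC quality threshold.
    """
    if n_controls < 0 or n_guides <= 0:
        raise ParameterError("n_guides must be positive and n_controls non-negative")
    if n_controls > n_guides:
        raise ParameterError("n_controls cannot exceed n_guides")
    n_target_genes = n_genes - (1 if n_controls > 0 else 0)
    n_target_guides = n_guides - n_controls
    if n_target_genes > n_target_guides:
        raise ParameterError(
            f"cannot target {n_target_genes} genes with {n_target_guides} non-control guides"
        )
    if n_target_genes < 1 and n_target_guides > 0:
        raise ParameterError("n_genes too small for the requested guides")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Unique protospacers with per-guide GC propensity ~ U(0.15, 0.75).
    protospacers: list[str] = []
    seen: set[str] = set()
    while len(protospacers) < n_guides:
        p_gc = rng.uniform(0.15, 0.75)
        probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
        idx = rng.choice(4, size=PROTOSPACER_LEN, p=probs)
        seq = bytes(DNA_ALPHABET[idx]).decode("ascii")
        if seq not in seen:
            seen.add(seq)
            protospacers.append(seq)

    guides: list[Guide] = []
    for i in range(n_controls):
        seq = protospacers[i]
        guides.append(
            Guide(
                guide_id=f"{CONTROL_GENE}_{i + 1:02d}",
                gene=CONTROL_GENE,
                protospacer=seq,
                gc_fraction=gc_fraction(seq),
                is_negative_control=True,
            )
        )

    # Round-robin assignment guarantees every gene gets >=1 guide.
    gene_names = [f"GENE{j + 1:04d}" for j in range(n_target_genes)]
    per_gene_counter: dict[str, int] = {g: 0 for g in gene_names}
    for k in range(n_target_guides):
        gene = gene_names[k % n_target_genes] if n_target_genes else CONTROL_GENE
        per_gene_counter[gene] += 1
        seq = protospacers[n_controls + k]
        guides.append(
            Guide(
                guide_id=f"{gene}_{per_gene_counter[gene]:02d}",
                gene=gene,
                protospacer=seq,
                gc_fraction=gc_fraction(seq),
                is_negative_control=False,
            )
        )
    return GuideLibrary(guides)


def load_guide_table(path) -> GuideLibrary:
    """Load a guide library from a TSV guide table.

    Accepts the column spellings used by published guide tables: guide id
    (``guide_id``/``guide``/``Guide``), target gene (``gene``/``Gene``) and
    optionally ``protospacer``/``sequence`` and ``gc_fraction``/``GC``.
    Guides whose gene is HO are treated as negative controls.  Missing GC
    fractions are computed from the protospacer.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    gid = pick("guide_id", "guide", "name")
    gene = pick("gene", "target", "target_gene")
    proto = pick("protospacer", "sequence", "spacer")
    gc = pick("gc_fraction", "gc", "gc content", "gc_content")
    if gid is None or gene is None:
        raise ParameterError("guide table needs guide and gene columns")
    guides = []
    protos = df[proto] if proto else ["A" * PROTOSPACER_LEN] * len(df)
    gcs = df[gc] if gc else [None] * len(df)
    for gid_v, gene_v, seq, gcv in zip(df[gid], df[gene], protos, gcs):
        seq = str(seq).upper()
        gene_name = str(gene_v)
        guides.append(
            Guide(
                guide_id=str(gid_v),
                gene=gene_name,
                protospacer=seq,
                gc_fraction=float(gcv) if gcv is not None else gc_fraction(seq),
                is_negative_control=gene_name.upper() == CONTROL_GENE,
            )
        )
    return GuideLibrary(guides)


def n_possible_pairs(n_guides: int) -> int:
    """Number of distinct unordered non-self guide pairs: n(n-1)/2."""
    return n_guides * (n_guides - 1) // 2


def enumerate_guide_pairs(library: GuideLibrary) -> list[tuple[str, str]]:
    """All distinct unordered non-self guide pairs in the library."""
    return list(itertools.combinations(library.guide_ids, 2))


def perturbation_id(guide_a: str, guide_b: str) -> str:
    """Canonical (order-free) identifier of an unordered guide pair."""
    first, second = sorted((guide_a, guide_b))
    return f"{first}+{second}"


def generate_constructs(
    library: GuideLibrary,
    n_pairs: int | None = None,
    pair_fraction: float | None = 0.77,
    barcodes_per_construct: int = 3,
    single_barcode_fraction: float = 0.05,
    control_partners: int = 3,
    include_control_pairs: bool = True,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample guide pairs and attach barcode pairs, one row per construct.

    The pair sample is deliberately structured rather than uniform: every
    control x control pair is included (these anchor the negative-control
    normalization), and every non-control guide is paired with
    ``control_partners`` distinct control guides (these provide single-guide
    phenotypes).  The remainder is drawn uniformly from the other possible
    pairs up to ``n_pairs`` (or ``pair_fraction`` of all possible pairs).

    Each sampled perturbation receives ``barcodes_per_construct`` barcode
    pairs, except a ``single_barcode_fraction`` of non-control perturbations
    that are forced down to a single barcode to exercise the >=2-barcode
    filter.  Control x control perturbations always keep their full barcode
    complement so the normalization reference cannot be filtered away.

    Returns a DataFrame with columns: construct_id, perturbation,
    guide_first, guide_second, barcode_ubc6, barcode_pcl5.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_pairs = enumerate_guide_pairs(library)
    if n_pairs is None:
        if pair_fraction is None:
            raise ParameterError("one of n_pairs or pair_fraction is required")
        n_pairs = int(round(pair_fraction * len(all_pairs)))
    if n_pairs < 1 or n_pairs > len(all_pairs):
        raise ParameterError(f"n_pairs must be in [1, {len(all_pairs)}]")

    control_set = set(library.control_ids)
    chosen: list[tuple[str, str]] = []
    chosen_set: set[tuple[str, str]] = set()

    def _add(pair: tuple[str, str]) -> None:
        key = tuple(sorted(pair))
        if key not in chosen_set:
            chosen_set.add(key)
            chosen.append(pair)

    if include_control_pairs and len(control_set) >= 2:
        for pair in itertools.combinations(sorted(control_set), 2):
            _add(pair)
    if control_partners > 0 and control_set:
        ctrl_sorted = sorted(control_set)
        for g in library.guide_ids:
            if g in control_set:
                continue
            k = min(control_partners, len(ctrl_sorted))
            partners = rng.choice(len(ctrl_sorted), size=k, replace=False)
            for j in partners:
                _add((g, ctrl_sorted[int(j)]))

    if len(chosen) > n_pairs:
        raise ParameterError(
            f"n_pairs={n_pairs} too small for the mandatory control pairings ({len(chosen)})"
        )
    remaining = [p for p in all_pairs if tuple(sorted(p)) not in chosen_set]
    n_extra = n_pairs - len(chosen)
    if n_extra > 0:
        idx = rng.choice(len(remaining), size=n_extra, replace=False)
        for j in sorted(idx):
            _add(remaining[int(j)])

    # Barcode multiplicity per perturbation.
    rows = []
    bc_u_seen: set[str] = set()
    bc_p_seen: set[str] = set()
    construct_counter = 0
    for g1, g2 in chosen:
        pert = perturbation_id(g1, g2)
        is_ctrl_pair = g1 in control_set and g2 in control_set
        n_bc = barcodes_per_construct
        if not is_ctrl_pair and rng.random() < single_barcode_fraction:
            n_bc = 1
        # Random construct orientation, as cloning does not order the guides.
        if rng.random() < 0.5:
            g1, g2 = g2, g1
        for _ in range(n_bc):
            while True:
                bu = random_dna(rng, BARCODE_LEN_UBC6)[0]
                if bu not in bc_u_seen:
                    bc_u_seen.add(bu)
                    break
            while True:
                bp = random_dna(rng, BARCODE_LEN_PCL5)[0]
                if bp not in bc_p_seen:
                    bc_p_seen.add(bp)
                    break
            construct_counter += 1
            rows.append(
                {
                    "construct_id": f"C{construct_counter:06d}",
                    "perturbation": pert,
                    "guide_first": g1,
                    "guide_second": g2,
                    "barcode_ubc6": bu,
                    "barcode_pcl5": bp,
                }
            )
    return pd.DataFrame(rows)
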