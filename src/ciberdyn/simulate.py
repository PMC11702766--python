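"""Generative model for a dual-reporter CiBER-seq screen.

The simulator produces, from a guide library, a construct table and a truth
model: (i) the UMI-deduplicated barcode x sample x reporter count table,
(ii) short reporter-amplicon reads (FASTQ) carrying an 8-nt UMI and the
expressed barcode, and (iii) long construct reads linking both barcodes to
the guide pair, as produced by long-read sequencing of the plasmid library.

Count model
-----------
Construct frequencies drift with fitness: at ``E`` hours after guide
induction a construct with pair growth effect ``gamma`` has frequency
proportional to ``f0 * 2**((1 + gamma) * E / t_d)`` where ``t_d`` is the
doubling time and ``f0`` a log-normal initial library representation.  The
UBC6 (normalizer) reporter is expressed at a constant level per cell; the
PCL5 (ISR) reporter at ``2**a`` where ``a`` is the construct's ISR activity
at the sample's dose and treatment time.  Each reporter amplicon receives
half the sample's sequencing depth, so expected counts are depth times the
expression share within the reporter.

Counts are negative binomial with dispersion ``phi`` (variance
``mu + phi * mu**2``), realized as a gamma-Poisson mixture whose gamma
factor is shared between the two reporters of a construct within a sample.
The shared factor models clone-abundance fluctuations (growth and harvest
stochasticity), which hit both barcodes of a cell equally and therefore
cancel in the matched PCL5:UBC6 ratio — the noise-cancellation property the
dual-reporter design exists to exploit.  Residual per-amplicon noise is
Poisson.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleMeta, post_induction_samples
from .library import (
    BARCODE_LEN_PCL5,
    BARCODE_LEN_UBC6,
    GuideLibrary,
    ParameterError,
    random_dna,
)
from .truth import TruthModel

REPORTER_UBC6 = "UBC6"
REPORTER_PCL5 = "PCL5"
REPORTERS = (REPORTER_UBC6, REPORTER_PCL5)

UMI_LENGTH = 8

# Fixed anchor 20-mers used by the simulated read layouts.  Reporter identity
# in short reads is encoded by which anchor follows the UMI.
SHORT_ANCHORS = {
    REPORTER_UBC6: "TCCACATGTGCATTGCCTCG",
    REPORTER_PCL5: "AGAGCTCGATCCAGTCACTC",
}
SHORT_FIXED_BASE = {REPORTER_UBC6: "A", REPORTER_PCL5: "C"}

# Constant vector sequence downstream of the barcode; reads run into it so
# every short read has the same fixed length regardless of barcode length.
SHORT_TAILS = {
    REPORTER_UBC6: "CCGAGGCAATGCACATGTGGAAGCTGGATCCA",
    REPORTER_PCL5: "CCAGAGTGACTGGATCGAGCTCTCTGGTACCA",
}
SHORT_READ_LENGTH = 75

# Long construct reads: a0 p1 a1 p2 a2 bc22 a3 bc23 a4
LONG_ANCHORS = (
    "GAACGAAACTCTGGGAGCTG",
    "GTTTAAGAGCTAAGCTGGAA",
    "CCGAGGCAATGCACATGTGG",
    "CTGGCGTTACCCAACGATAA",
    "CCAGAGTGACTGGATCGAGC",
)

FASTQ_QUAL_CHAR = "F"  # Phred+33, Q37


@dataclass
class SimConfig:
    """Knobs of the generative model (rates, depths, noise levels)."""

    library_size_per_sample: int = 2_000_000
    nb_dispersion: float = 0.05  # phi; var = mu + phi mu^2
    base_error_rate: float = 0.001  # per-base substitution probability
    chimera_rate: float = 0.01  # long reads with a foreign PCL5-side barcode
    doubling_time_h: float = 2.0
    initial_abundance_sd_log2: float = 0.5
    umi_duplication_mean: float = 0.5  # extra reads per molecule, Poisson
    long_read_depth_mean: float = 12.0
    dose_growth_penalty: float = 0.0  # optional extra depletion per treated hour
    reporter_floor_log2: float = -5.0  # leaky floor of the PCL5 reporter
    reporter_ceiling_log2: float = 5.0  # fully induced ceiling of the PCL5 reporter
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("base_error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be >= 0")
        if self.library_size_per_sample < 0:
            raise ParameterError("library_size_per_sample must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class ScreenSim:
    """Bundle of simulated screen outputs."""

    counts: pd.DataFrame  # construct_id, reporter, one column per sample
    expected: pd.DataFrame  # same layout, noise-free expectations
    manifest: pd.DataFrame  # per construct: guides, barcodes, truth columns
    truth_phenotypes: pd.DataFrame  # perturbation x sample truth table
    design: list
    config: SimConfig


def _pair_arrays(constructs: pd.DataFrame, truth: TruthModel):
    """Per-construct truth parameter arrays, summed over the guide pair."""
    g1 = constructs["guide_first"].to_numpy()
    g2 = constructs["guide_second"].to_numpy()
    t = truth.guides
    missing = (set(g1) | set(g2)) - set(t.index)
    if missing:
        raise ParameterError(f"constructs reference guides without truth: {sorted(missing)[:5]}")
    p1 = t.loc[g1]
    p2 = t.loc[g2]
    eta = np.array([truth.eta(a, b) for a, b in zip(g1, g2)])
    gamma = p1["growth_effect"].to_numpy() + p2["growth_effect"].to_numpy()
    return p1, p2, eta, gamma


def _pair_activity_arrays(p1, p2, eta, dose: float, time_h: float) -> np.ndarray:
    from .truth import activity_surface

    a1 = activity_surface(
        p1["basal_isr"].to_numpy(),
        p1["amplitude"].to_numpy(),
        p1["ec50"].to_numpy(),
        p1["hill"].to_numpy(),
        p1["onset_h"].to_numpy(),
        p1["adaptation"].to_numpy(),
        dose,
        time_h,
    )
    a2 = activity_surface(
        p2["basal_isr"].to_numpy(),
        p2["amplitude"].to_numpy(),
        p2["ec50"].to_numpy(),
        p2["hill"].to_numpy(),
        p2["onset_h"].to_numpy(),
        p2["adaptation"].to_numpy(),
        dose,
        time_h,
    )
    return a1 + a2 + eta


def expected_counts_for_sample(
    sample: SampleMeta,
    freq0: np.ndarray,
    gamma: np.ndarray,
    activity: np.ndarray,
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected (UBC6, PCL5) counts for one sample."""
    induced = sample.phase != "pre_induction"
    e_dbl = sample.elapsed_h / cfg.doubling_time_h
    log2_growth = (1.0 + (gamma if induced else np.zeros_like(gamma))) * e_dbl
    if cfg.dose_growth_penalty > 0 and sample.phase == "treated":
        log2_growth = log2_growth - cfg.dose_growth_penalty * (
            sample.dose / (sample.dose + 1.0)
        ) * (sample.time_h / cfg.doubling_time_h)
    w = freq0 * np.exp2(log2_growth - log2_growth.max())
    freq = w / w.sum()
    half = cfg.library_size_per_sample / 2.0
    mu_u = half * freq
    wp = freq * np.exp2(activity)
    mu_p = half * wp / wp.sum()
    return mu_u, mu_p


def simulate_counts(
    constructs: pd.DataFrame,
    truth: TruthModel,
    design: list,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the UMI-deduplicated count table; returns (counts, expected)."""
    rng = rng if rng is not None else cfg.rng()
    n = len(constructs)
    p1, p2, eta, gamma = _pair_arrays(constructs, truth)
    freq0 = np.exp2(rng.normal(0.0, cfg.initial_abundance_sd_log2, size=n))
    freq0 = freq0 / freq0.sum()

    if cfg.library_size_per_sample == 0:
        warnings.warn("library_size_per_sample is 0: all counts will be zero")

    counts = {
        "construct_id": np.concatenate([constructs["construct_id"].to_numpy()] * 2),
        "reporter": np.array([REPORTER_UBC6] * n + [REPORTER_PCL5] * n),
    }
    expected = dict(counts)

    from .truth import reporter_response

    for s in design:
        if s.phase == "pre_induction":
            act = np.zeros(n)
        else:
            dose = s.dose if s.phase == "treated" else 0.0
            t = s.time_h if s.time_h is not None else 0.0
            act = reporter_response(
                _pair_activity_arrays(p1, p2, eta, dose, t),
                cfg.reporter_floor_log2,
                cfg.reporter_ceiling_log2,
            )
        mu_u, mu_p = expected_counts_for_sample(s, freq0, gamma, act, cfg)
        if cfg.nb_dispersion > 0:
            shared = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion, size=n)
        else:
            shared = 1.0
        c_u = rng.poisson(mu_u * shared)
        c_p = rng.poisson(mu_p * shared)
        counts[s.sample_id] = np.concatenate([c_u, c_p])
        expected[s.sample_id] = np.concatenate([mu_u, mu_p])
    return pd.DataFrame(counts), pd.DataFrame(expected)


def build_manifest(constructs: pd.DataFrame, truth: TruthModel, library: GuideLibrary) -> pd.DataFrame:
    """Per-construct manifest with truth columns and barcode multiplicity."""
    man = constructs.copy()
    p1, p2, eta, gamma = _pair_arrays(constructs, truth)
    man["class_first"] = p1["class_label"].to_numpy()
    man["class_second"] = p2["class_label"].to_numpy()
    man["gamma_pair"] = gamma
    man["basal_isr_pair"] = p1["basal_isr"].to_numpy() + p2["basal_isr"].to_numpy() + eta
    man["eta"] = eta
    ctrl = set(library.control_ids)
    man["is_control_pair"] = [
        (a in ctrl) and (b in ctrl) for a, b in zip(man["guide_first"], man["guide_second"])
    ]
    n_bc = man.groupby("perturbation")["construct_id"].transform("size")
    man["n_barcodes"] = n_bc
    man["single_barcode"] = n_bc == 1
    return man


def truth_phenotype_table(
    constructs: pd.DataFrame, truth: TruthModel, design: list, cfg: SimConfig
) -> pd.DataFrame:
    """Per (perturbation, post-induction sample) true ISR and growth log2FC.

    Growth truth is expressed the way the estimator reports it: log2
    frequency change versus the pre-induction sample, relative to neutral
    (control) constructs, i.e. ``gamma_pair * elapsed_h / doubling_time``.
    ISR truth is the reporter-level readout — the latent additive pair
    activity passed through the reporter's saturating transfer — relative to
    the control (zero-activity) reporter output, which is the estimand of
    the control-normalized matched-reporter log ratio.
    """
    from .truth import reporter_response

    pairs = constructs.drop_duplicates("perturbation")
    p1, p2, eta, gamma = _pair_arrays(pairs, truth)
    zero = reporter_response(0.0, cfg.reporter_floor_log2, cfg.reporter_ceiling_log2)
    rows = []
    for s in post_induction_samples(design):
        dose = s.dose if s.phase == "treated" else 0.0
        t = s.time_h if s.time_h is not None else 0.0
        act = (
            reporter_response(
                _pair_activity_arrays(p1, p2, eta, dose, t),
                cfg.reporter_floor_log2,
                cfg.reporter_ceiling_log2,
            )
            - zero
        )
        growth = gamma * (s.elapsed_h / cfg.doubling_time_h)
        rows.append(
            pd.DataFrame(
                {
                    "perturbation": pairs["perturbation"].to_numpy(),
                    "sample_id": s.sample_id,
                    "isr_true": act,
                    "growth_true": growth,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_screen(
    library: GuideLibrary,
    constructs: pd.DataFrame,
    truth: TruthModel,
    design: list,
    cfg: SimConfig,
) -> ScreenSim:
    """Run the count-level simulation and assemble the output bundle."""
    rng = cfg.rng()
    counts, expected = simulate_counts(constructs, truth, design, cfg, rng)
    manifest = build_manifest(constructs, truth, library)
    pheno = truth_phenotype_table(constructs, truth, design, cfg)
    return ScreenSim(
        counts=counts,
        expected=expected,
        manifest=manifest,
        truth_phenotypes=pheno,
        design=design,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply independent per-base substitutions at the given rate."""
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def short_read_sequence(umi: str, reporter: str, barcode: str, read_length: int = SHORT_READ_LENGTH) -> str:
    """Assemble an error-free short reporter read of fixed length."""
    seq = umi + SHORT_FIXED_BASE[reporter] + SHORT_ANCHORS[reporter] + barcode + SHORT_TAILS[reporter]
    return seq[:read_length]


def long_read_sequence(protospacer1: str, protospacer2: str, bc_ubc6: str, bc_pcl5: str) -> str:
    """Assemble an error-free long construct read."""
    a0, a1, a2, a3, a4 = LONG_ANCHORS
    return a0 + protospacer1 + a1 + protospacer2 + a2 + bc_ubc6 + a3 + bc_pcl5 + a4


def _write_fastq(path, records) -> int:
    n = 0
    with gzip.open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{FASTQ_QUAL_CHAR * len(seq)}\n")
            n += 1
    return n


def write_short_reads(
    sim: ScreenSim,
    outdir,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
) -> dict:
    """Emit per-sample gzipped FASTQ of short reporter reads.

    Each deduplicated count is one cDNA molecule with its own random 8-nt
    UMI; PCR duplication re-emits a molecule 1 + Poisson(umi_duplication_mean)
    times with the same UMI.  Substitution errors are applied per base.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 1)
    barcodes = {
        REPORTER_UBC6: sim.manifest.set_index("construct_id")["barcode_ubc6"],
        REPORTER_PCL5: sim.manifest.set_index("construct_id")["barcode_pcl5"],
    }
    sample_ids = samples or [s.sample_id for s in sim.design]
    paths = {}
    for sample_id in sample_ids:
        records = []
        sub = sim.counts[["construct_id", "reporter", sample_id]]
        ridx = 0
        for row in sub.itertuples(index=False):
            c = int(getattr(row, sample_id))
            if c <= 0:
                continue
            bc = barcodes[row.reporter].loc[row.construct_id]
            umis = random_dna(rng, UMI_LENGTH, c)
            dups = 1 + rng.poisson(cfg.umi_duplication_mean, size=c)
            for umi, d in zip(umis, dups):
                clean = short_read_sequence(umi, row.reporter, bc)
                for _ in range(int(d)):
                    records.append((f"S{ridx}", _mutate(clean, rng, cfg.base_error_rate)))
                    ridx += 1
        path = outdir / f"{sample_id}.fastq.gz"
        _write_fastq(path, records)
        paths[sample_id] = path
    return paths


def write_long_reads(
    manifest: pd.DataFrame,
    cfg: SimConfig,
    path,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit long construct reads (gzipped FASTQ); returns chimera records.

    Per-construct support is Poisson(long_read_depth_mean).  A
    ``chimera_rate`` fraction of reads are template-switch artifacts whose
    PCL5-side barcode is taken from a different construct, creating a novel
    (and spurious) barcode pairing that downstream mapping must reject.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 2)
    protos1 = manifest["proto_first"].to_numpy()
    protos2 = manifest["proto_second"].to_numpy()
    bcu = manifest["barcode_ubc6"].to_numpy()
    bcp = manifest["barcode_pcl5"].to_numpy()
    n = len(manifest)
    support = rng.poisson(cfg.long_read_depth_mean, size=n)
    chimeras = []
    ridx = 0
    with gzip.open(path, "wt") as fh:
        for i in range(n):
            for _ in range(int(support[i])):
                pcl5_bc = bcp[i]
                if n > 1 and rng.random() < cfg.chimera_rate:
                    j = int(rng.integers(0, n - 1))
                    if j >= i:
                        j += 1
                    pcl5_bc = bcp[j]
                    chimeras.append({"barcode_ubc6": bcu[i], "barcode_pcl5": pcl5_bc})
                seq = _mutate(
                    long_read_sequence(protos1[i], protos2[i], bcu[i], pcl5_bc),
                    rng,
                    cfg.base_error_rate,
                )
                fh.write(f"@L{ridx}\n{seq}\n+\n{FASTQ_QUAL_CHAR * len(seq)}\n")
                ridx += 1
    return pd.DataFrame(chimeras, columns=["barcode_ubc6", "barcode_pcl5"])


def manifest_with_protospacers(manifest: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Attach protospacer sequences needed for long-read simulation."""
    out = manifest.copy()
    out["proto_first"] = [library[g].protospacer for g in out["guide_first"]]
    out["proto_second"] = [library[g].protospacer for g in out["guide_second"]]
    return out
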