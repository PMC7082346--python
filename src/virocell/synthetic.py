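"""Synthetic data with known ground truth for the whole pipeline.

Two generator families:

* **Genomes.** Host coding sequences are sampled codon-by-codon from a
  per-amino-acid codon-usage profile; a matched phage genome reuses the
  host profile but moves a controlled amount of probability mass delta
  within the synonymous families of chosen target codons. Amino-acid
  composition is held fixed, so divergence is purely at the codon level —
  exactly the signal the codon-impact measure is meant to pick up.

* **Expression time courses.** Replicated infected/uninfected gene-count
  matrices with negative-binomial noise, planted early/middle/late temporal
  clusters for phage genes, known per-gene true log2 fold changes, and a
  known infected fraction f: the observed infected mean is the mixture
  f * virocell + (1 - f) * control that ``adjusted_fold_change`` inverts.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import CODONS, genetic_code, synonymous_families
from .genome_io import CdsFeature, GenomeRecord, reverse_complement, write_genbank

# typical bacterial amino-acid composition (rounded, sums to 1)
DEFAULT_AA_COMPOSITION: dict[str, float] = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.040, "E": 0.060, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.102, "K": 0.047, "M": 0.027, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.014, "Y": 0.028, "V": 0.075,
}


def default_codon_profile(table_id: int = 11) -> dict[str, dict[str, float]]:
    """A biased but realistic within-family codon-usage profile.

    Codons are weighted by an AT-leaning base composition and the weights
    sharpened so every multi-codon family shows usable bias.
    """
    base_w = {"A": 0.30, "T": 0.30, "G": 0.20, "C": 0.20}
    profile: dict[str, dict[str, float]] = {}
    for aa, fam in synonymous_families(table_id).items():
        w = np.array([np.prod([base_w[b] for b in c]) for c in fam])
        w = w**1.5
        w /= w.sum()
        profile[aa] = {c: float(x) for c, x in zip(fam, w)}
    return profile


@dataclass
class GenomeSimSpec:
    """Parameters for one synthetic genome (host or phage)."""

    genome_id: str = "synth_host"
    n_cds: int = 300
    cds_len_mean: int = 300  # codons
    cds_len_sd: int = 60
    aa_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_COMPOSITION)
    )
    codon_profile: dict[str, dict[str, float]] = field(
        default_factory=default_codon_profile
    )
    delta: float = 0.0
    target_codons: tuple[str, ...] = ()
    translation_table: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds <= 0:
            raise ValueError("n_cds must be positive")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        for aa, fam in self.codon_profile.items():
            if abs(sum(fam.values()) - 1.0) > 1e-9:
                raise ValueError(f"codon profile for {aa!r} does not sum to 1")
        if abs(sum(self.aa_composition.values()) - 1.0) > 1e-6:
            raise ValueError("amino-acid composition does not sum to 1")


@dataclass
class ExpressionSimSpec:
    """Parameters for a replicated infected/uninfected count time course."""

    n_host_genes: int = 200
    n_phage_genes: int = 60
    time_points: tuple[int, ...] = (0, 15, 30, 45, 60)
    treatments: tuple[str, ...] = ("uninfected", "HP1")
    n_replicates: int = 3
    de_fraction: float = 0.3
    max_abs_log2fc: float = 3.0
    infected_fraction: float | dict[int, float] = 0.95
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu^2; 0 = noiseless
    baseline_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.infected_fraction
        fs = list(f.values()) if isinstance(f, dict) else [f]
        if any(not 0 < x <= 1 for x in fs):
            raise ValueError("infected fraction must lie in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.time_points) < 3:
            raise ValueError("need at least 3 timepoints")


@dataclass
class SyntheticTruth:
    """Ground-truth record attached to generated data."""

    shifted_codons: tuple[str, ...] = ()
    realized_dc: float | None = None
    cluster_ids: pd.Series | None = None
    stage_labels: pd.Series | None = None
    true_log2fc: pd.DataFrame | None = None
    infected_fraction: pd.Series | None = None


# ---------------------------------------------------------------------------
# genome generators
# ---------------------------------------------------------------------------


def _flat_codon_probs(spec: GenomeSimSpec) -> np.ndarray:
    """Overall non-stop codon sampling distribution implied by the spec."""
    code = genetic_code(spec.translation_table)
    p = np.zeros(64)
    for i, codon in enumerate(CODONS):
        aa = code[codon]
        if aa == "*":
            continue
        p[i] = spec.aa_composition.get(aa, 0.0) * spec.codon_profile[aa][codon]
    return p / p.sum()


def _stop_probs(spec: GenomeSimSpec) -> tuple[list[str], np.ndarray]:
    fam = spec.codon_profile["*"]
    codons = list(fam)
    p = np.array([fam[c] for c in codons])
    return codons, p / p.sum()


def synth_host(
    spec: GenomeSimSpec, out_path: str | Path | None = None
) -> tuple[GenomeRecord, list[CdsFeature], Path | None]:
    """Generate a genome with CDS sampled codon-by-codon from the profile.

    CDS alternate strands along the genome with 20 nt intergenic spacers;
    every CDS starts with ATG and ends with a stop drawn from the stop
    family's usage. Deterministic under ``spec.seed``; if ``out_path`` is
    given the genome is written as GenBank and re-readable by genome_io.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _flat_codon_probs(spec)
    stop_codons, stop_p = _stop_probs(spec)
    codon_arr = np.array(CODONS)

    lengths = np.maximum(
        30, rng.normal(spec.cds_len_mean, spec.cds_len_sd, spec.n_cds).astype(int)
    )
    spacer_p = np.array([0.3, 0.2, 0.2, 0.3])  # A C G T
    bases = np.array(list("ACGT"))

    chunks: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for i, n_codons in enumerate(lengths):
        spacer = "".join(rng.choice(bases, size=20, p=spacer_p))
        chunks.append(spacer)
        pos += 20
        body_idx = rng.choice(64, size=n_codons - 2, p=probs)
        stop = rng.choice(stop_codons, p=stop_p)
        coding = "ATG" + "".join(codon_arr[body_idx]) + stop
        strand = "+" if i % 2 == 0 else "-"
        placed = coding if strand == "+" else reverse_complement(coding)
        start, end = pos, pos + len(coding)
        chunks.append(placed)
        pos = end
        features.append(
            CdsFeature(
                genome_id=spec.genome_id,
                locus_tag=f"{spec.genome_id}_{i:04d}",
                product="hypothetical protein",
                intervals=[(start, end)],
                strand=strand,
                translation_table=spec.translation_table,
            )
        )
    chunks.append("".join(rng.choice(bases, size=20, p=spacer_p)))
    genome = GenomeRecord(
        genome_id=spec.genome_id,
        description=f"synthetic genome ({spec.n_cds} CDS)",
        sequence="".join(chunks),
    )
    path = None
    if out_path is not None:
        path = write_genbank(genome, features, out_path)
    return genome, features, path


def shift_codon_profile(
    profile: dict[str, dict[str, float]],
    target_codons: tuple[str, ...],
    delta: float,
    table_id: int = 11,
) -> dict[str, dict[str, float]]:
    """Move probability mass delta toward each target codon within its family.

    The target's usage becomes p + delta * (1 - p); the rest of the family
    is rescaled to keep the family summing to 1. delta = 0 is the identity,
    delta = 1 concentrates the family on the target.
    """
    code = genetic_code(table_id)
    fams = synonymous_families(table_id)
    for c in target_codons:
        if len(fams[code[c]]) < 2:
            raise ValueError(f"target codon {c} is in a single-codon family")
    out = {aa: dict(fam) for aa, fam in profile.items()}
    for c in target_codons:
        aa = code[c]
        fam = out[aa]
        p_old = fam[c]
        p_new = p_old + delta * (1.0 - p_old)
        rest = 1.0 - p_old
        scale = (1.0 - p_new) / rest if rest > 0 else 0.0
        for codon in fam:
            fam[codon] = p_new if codon == c else fam[codon] * scale
    return out


def synth_phage_from_host(
    host_spec: GenomeSimSpec,
    delta: float,
    target_codons: tuple[str, ...] | None = None,
    seed: int = 1,
    genome_id: str = "synth_phage",
    n_cds: int = 100,
    host: tuple[GenomeRecord, list[CdsFeature]] | None = None,
) -> tuple[GenomeRecord, list[CdsFeature], SyntheticTruth]:
    """Generate a phage genome diverged from the host's codon profile.

    The phage reuses the host amino-acid composition and codon profile with
    ``delta`` probability mass shifted toward each target codon (default: 6
    codons drawn from distinct multi-codon families). Realized D_c between
    the generated genomes is recorded in the returned truth.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if target_codons is None:
        # identifiable plants: the most-used amino acids (the shift must
        # stand above multinomial sampling noise) restricted to families of
        # >= 4 codons — in small families the compensating sibling shift
        # p_sib/(1-p_target) approaches the target's own change, so target
        # and siblings become intrinsically hard to separate; within the
        # family, the least-used codon leaves the most mass to move.
        fams = synonymous_families(host_spec.translation_table)
        eligible = sorted(
            (
                aa
                for aa, fam in fams.items()
                if aa != "*" and len(fam) >= 4
            ),
            key=lambda aa: -host_spec.aa_composition.get(aa, 0.0),
        )
        chosen_fams = eligible[:6]
        target_codons = tuple(
            min(fams[aa], key=lambda c: host_spec.codon_profile[aa][c])
            for aa in chosen_fams
        )
    profile = shift_codon_profile(
        host_spec.codon_profile,
        tuple(target_codons),
        delta,
        host_spec.translation_table,
    )
    phage_spec = replace(
        host_spec,
        genome_id=genome_id,
        n_cds=n_cds,
        codon_profile=profile,
        delta=delta,
        target_codons=tuple(target_codons),
        seed=seed,
    )
    phage, phage_cds, _ = synth_host(phage_spec)

    from . import complementarity, genome_io

    if host is None:
        host = synth_host(host_spec)[:2]
    dc = None
    hg, hf = host
    v = []
    for g, feats in ((phage, phage_cds), (hg, hf)):
        seqs = [genome_io.extract_cds_sequence(g, c) for c in feats]
        v.append(
            complementarity.relative_frequencies(
                genome_io.count_codons(seqs, g.genome_id)
            )
        )
    dc = complementarity.cosine_distance(v[0], v[1])
    truth = SyntheticTruth(shifted_codons=tuple(target_codons), realized_dc=dc)
    return phage, phage_cds, truth


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

_STAGE_TEMPLATES = {
    # unit-scale temporal shapes over a [0, 1] time axis
    "early": lambda x: np.exp(-(((x - 0.1) / 0.18) ** 2)),
    "middle": lambda x: np.exp(-(((x - 0.5) / 0.18) ** 2)),
    "late": lambda x: np.exp(-(((x - 0.95) / 0.25) ** 2)),
}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB draw with var = mu + dispersion mu^2; dispersion 0 is noiseless."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)).astype(np.int64)


def synth_expression(
    spec: ExpressionSimSpec,
) -> tuple["CountMatrix", pd.DataFrame, SyntheticTruth]:
    """Generate a replicated infected/uninfected count time course.

    Host-gene control means follow a lognormal baseline (clipped below at
    half the baseline mean, so the +1 fold-change pseudocount stays
    negligible even for strongly down-regulated genes); virocell
    means are baseline * 2^trueFC with fold changes ramping up over the
    time course for a planted DE fraction. Phage genes express only in
    infected cultures, following early/middle/late stage templates. The
    observed infected mean is the f-mixture of virocell and control.

    Returns the combined CountMatrix (all treatments), gene annotation
    (lengths and strata) and the ground truth.
    """
    from .expression import CountMatrix

    rng = np.random.default_rng(spec.seed)
    times = np.array(spec.time_points, dtype=float)
    x = (times - times.min()) / max(times.max() - times.min(), 1.0)
    host_genes = [f"host_{i:04d}" for i in range(spec.n_host_genes)]
    phage_genes = [f"phage_{i:04d}" for i in range(spec.n_phage_genes)]

    f = spec.infected_fraction
    f_series = pd.Series(
        {t: (f[t] if isinstance(f, dict) else f) for t in spec.time_points},
        dtype=float,
    )

    # host truth: baseline and ramping fold changes for a DE subset
    baseline = np.clip(
        rng.lognormal(np.log(spec.baseline_mean), 0.6, spec.n_host_genes),
        0.5 * spec.baseline_mean,
        None,
    )
    n_de = int(round(spec.de_fraction * spec.n_host_genes))
    de_idx = rng.choice(spec.n_host_genes, size=n_de, replace=False)
    peak_fc = np.zeros(spec.n_host_genes)
    peak_fc[de_idx] = rng.uniform(1.0, spec.max_abs_log2fc, n_de) * rng.choice(
        [-1.0, 1.0], n_de
    )
    ramp = x  # fold change grows linearly over the course of infection
    true_fc = pd.DataFrame(
        np.outer(peak_fc, ramp), index=host_genes, columns=spec.time_points
    )

    # phage truth: planted stages
    stages = np.array(
        [list(_STAGE_TEMPLATES)[i % 3] for i in range(spec.n_phage_genes)]
    )
    phage_scale = rng.lognormal(np.log(800.0), 0.4, spec.n_phage_genes)
    phage_mean = np.stack(
        [phage_scale[i] * (_STAGE_TEMPLATES[stages[i]](x) + 0.02) for i in range(spec.n_phage_genes)]
    )

    infected_treatments = [t for t in spec.treatments if t != "uninfected"]
    columns, col_meta = [], []
    count_cols: dict[str, np.ndarray] = {}
    for trt in spec.treatments:
        for ti, t in enumerate(spec.time_points):
            for rep in range(1, spec.n_replicates + 1):
                name = f"{trt}_t{t}_r{rep}"
                control_mean = baseline
                if trt == "uninfected":
                    host_mean = control_mean
                    ph_mean = np.zeros(spec.n_phage_genes)
                else:
                    virocell = baseline * 2.0 ** true_fc[t].to_numpy()
                    ft = f_series[t]
                    host_mean = ft * virocell + (1 - ft) * control_mean
                    ph_mean = ft * phage_mean[:, ti]
                mu = np.concatenate([host_mean, ph_mean])
                count_cols[name] = _nb_sample(rng, mu, spec.dispersion)
                columns.append(name)
                col_meta.append((name, trt, t, rep))
    values = pd.DataFrame(count_cols, index=host_genes + phage_genes)
    samples = pd.DataFrame(
        col_meta, columns=["sample_id", "treatment", "time_min", "replicate"]
    ).set_index("sample_id")
    counts = CountMatrix(values=values, samples=samples)

    annotation = pd.DataFrame(
        {
            "length_bp": np.concatenate(
                [
                    rng.integers(300, 3000, spec.n_host_genes),
                    rng.integers(200, 2000, spec.n_phage_genes),
                ]
            ),
            "stratum": ["host"] * spec.n_host_genes + ["phage"] * spec.n_phage_genes,
        },
        index=host_genes + phage_genes,
    )
    stage_order = {"early": 1, "middle": 2, "late": 3}
    truth = SyntheticTruth(
        cluster_ids=pd.Series(
            [stage_order[s] for s in stages], index=phage_genes, name="cluster"
        ),
        stage_labels=pd.Series(stages, index=phage_genes, name="stage"),
        true_log2fc=true_fc,
        infected_fraction=f_series,
    )
    _ = infected_treatments
    return counts, annotation, truth


def synth_trend_design(
    effect_sizes: dict[str, float] | None = None,
    slope: float = 0.0,
    sigma: float = 1.0,
    treatments: tuple[str, ...] = ("uninfected", "HP1", "HS2"),
    time_points: tuple[int, ...] = (0, 30, 60),
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-sample total-count design for the trend model.

    ``effect_sizes`` gives each non-reference treatment's mean shift in
    units of the residual sd; the default (None) is a null design with no
    treatment or time effect.
    """
    rng = np.random.default_rng(seed)
    effect_sizes = effect_sizes or {}
    rows = []
    for trt in treatments:
        shift = effect_sizes.get(trt, 0.0) * sigma
        for t in time_points:
            for rep in range(1, n_replicates + 1):
                y = 100.0 + shift + slope * t + rng.normal(0, sigma)
                rows.append((y, trt, t, rep))
    return pd.DataFrame(
        rows, columns=["response", "treatment", "time_min", "replicate"]
    )
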