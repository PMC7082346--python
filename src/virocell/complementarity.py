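"""Phage-host codon-usage complementarity.

The core statistic is the cosine distance D_c between the 64-dimensional
codon relative-frequency vectors of a phage and its host: D_c = 0 for
identical codon usage, approaching 1 for orthogonal usage. To attribute the
distance to individual codons, each phage codon frequency is substituted in
turn by the host's value and the distance re-measured; the absolute change

    delta_c = | D_c(phage', host) - D_c(phage, host) |

is that codon's *impact* on the overall phage-host codon mismatch. The
substituted vector is not renormalized: cosine distance is insensitive to
overall scale, and the substitution is a literal single-entry replacement.

Group-level contrasts of impact distributions (e.g. one phage-host pair
against a panel of pairs, or viral families against each other) use pairwise
independent t-tests or Wilcoxon rank-sum tests with Holm-Bonferroni
adjustment across the whole family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import genome_io
from .codons import CODONS, genetic_code, synonymous_families


@dataclass
class CodonFrequencyVector:
    """Relative codon frequencies in canonical (alphabetical) order."""

    genome_id: str
    freqs: np.ndarray  # shape (64,)
    total_codons: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (64,):
            raise ValueError("frequency vector must have 64 entries")
        if (self.freqs < 0).any():
            raise ValueError("negative frequency")
        if self.total_codons > 0 and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


@dataclass
class RscuTable:
    """RSCU per codon; ``None`` marks a synonymous family never observed."""

    genome_id: str
    rscu: dict[str, float | None]


@dataclass
class CodonImpactProfile:
    """Base distance D_c plus per-codon substitution impacts for one pair."""

    phage_id: str
    host_id: str
    base_distance: float
    impact: dict[str, float]
    phage_freqs: dict[str, float] = field(default_factory=dict)


@dataclass
class PairComplementarityResult:
    phage_id: str
    host_id: str
    d_c: float
    gc_phage: float
    gc_host: float
    profile: CodonImpactProfile
    aa_impacts: dict[str, list[tuple[str, float, float]]]
    family: str = "unknown"


@dataclass
class GroupComparisonResult:
    group_a: str
    group_b: str
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str = "holm_bonferroni"


def relative_frequencies(counts: genome_io.CodonCountTable) -> CodonFrequencyVector:
    """Each codon's count divided by the total codon count (all 64 cells)."""
    total = counts.total
    if total == 0:
        raise ValueError(f"{counts.genome_id}: zero codons; frequencies undefined")
    vec = np.array([counts.counts[c] for c in CODONS], dtype=float) / total
    return CodonFrequencyVector(counts.genome_id, vec, total)


def rscu(counts: genome_io.CodonCountTable, table_id: int = 11) -> RscuTable:
    """Relative Synonymous Codon Usage.

    For codon j in a synonymous family of size n with counts X:
    RSCU_j = X_j / ((1/n) * sum(X)). Families with zero total (including the
    single-codon Met/Trp families when unobserved) are marked undefined.
    """
    out: dict[str, float | None] = {}
    for _aa, fam in synonymous_families(table_id).items():
        fam_total = sum(counts.counts[c] for c in fam)
        if fam_total == 0:
            for c in fam:
                out[c] = None
        else:
            expected = fam_total / len(fam)
            for c in fam:
                out[c] = counts.counts[c] / expected
    return RscuTable(counts.genome_id, out)


def _as_array(v) -> np.ndarray:
    return v.freqs if isinstance(v, CodonFrequencyVector) else np.asarray(v, float)


def cosine_distance(v_phage, v_host) -> float:
    """D_c = 1 - cos(angle) between two codon-frequency vectors.

    Symmetric; 0 for identical usage; within [0, 1] for non-negative
    vectors. Raises on a zero-norm vector.
    """
    a, b = _as_array(v_phage), _as_array(v_host)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def codon_impact(v_phage, v_host) -> CodonImpactProfile:
    """Per-codon substitution impact on the phage-host cosine distance.

    For each codon, the phage vector's entry is set to the host's value
    (other entries untouched, no renormalization) and D_c re-measured;
    the impact is the absolute change from the base distance.
    """
    a, b = _as_array(v_phage), _as_array(v_host)
    base = cosine_distance(a, b)
    impact: dict[str, float] = {}
    for i, codon in enumerate(CODONS):
        sub = a.copy()
        sub[i] = b[i]
        impact[codon] = abs(cosine_distance(sub, b) - base)
    phage_id = getattr(v_phage, "genome_id", "")
    host_id = getattr(v_host, "genome_id", "")
    return CodonImpactProfile(
        phage_id=phage_id,
        host_id=host_id,
        base_distance=base,
        impact=impact,
        phage_freqs={c: float(a[i]) for i, c in enumerate(CODONS)},
    )


def aggregate_by_amino_acid(
    profile: CodonImpactProfile, table_id: int = 11
) -> dict[str, list[tuple[str, float, float]]]:
    """Group codon impacts by encoded amino acid (stop under ``*``).

    Every one of the 64 codons lands in exactly one bucket; within a bucket,
    entries (codon, impact, phage codon frequency) are sorted by impact
    descending, ties broken alphabetically by codon.
    """
    code = genetic_code(table_id)
    buckets: dict[str, list[tuple[str, float, float]]] = {}
    for codon in CODONS:
        buckets.setdefault(code[codon], []).append(
            (codon, profile.impact[codon], profile.phage_freqs.get(codon, 0.0))
        )
    for aa in buckets:
        buckets[aa].sort(key=lambda t: (-t[1], t[0]))
    return buckets


def compare_groups(
    impact_sets: dict[str, list[float]],
    method: str = "t_test",
    welch: bool = True,
) -> list[GroupComparisonResult]:
    """All-pairs two-sided group comparisons with Holm-Bonferroni adjustment.

    ``method`` is ``"t_test"`` (independent-samples t; Welch by default,
    pooled-variance Student with ``welch=False``) or ``"wilcoxon"``
    (rank-sum / Mann-Whitney U). The step-down Holm adjustment is applied
    across the whole family of pairwise comparisons.
    """
    if method not in ("t_test", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    if len(impact_sets) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in impact_sets.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    pairs = list(combinations(sorted(impact_sets), 2))
    stats_p = []
    for a, b in pairs:
        x, y = np.asarray(impact_sets[a], float), np.asarray(impact_sets[b], float)
        if method == "t_test":
            res = stats.ttest_ind(x, y, equal_var=not welch)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat = float(res.statistic)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        stats_p.append((stat, p))
    raw = [p for _, p in stats_p]
    adjusted = multipletests(raw, method="holm")[1]
    return [
        GroupComparisonResult(a, b, method, s, p, float(padj))
        for (a, b), (s, p), padj in zip(pairs, stats_p, adjusted)
    ]


def _load_member(member):
    """A pair member is a GenBank path or a (GenomeRecord, [CdsFeature])."""
    if isinstance(member, (str, Path)):
        return genome_io.read_genbank(member)
    genome, features = member
    return genome, list(features)


def pair_analysis(phage, host, family: str = "unknown") -> PairComplementarityResult:
    """Full complementarity analysis for one phage-host pair."""
    pg, pf = _load_member(phage)
    hg, hf = _load_member(host)
    if not pf or not hf:
        who = pg.genome_id if not pf else hg.genome_id
        raise ValueError(f"{who}: no CDS annotation; codon usage undefined")
    v = {}
    for genome, feats in ((pg, pf), (hg, hf)):
        seqs = [genome_io.extract_cds_sequence(genome, c) for c in feats]
        v[genome.genome_id] = relative_frequencies(
            genome_io.count_codons(seqs, genome.genome_id)
        )
    profile = codon_impact(v[pg.genome_id], v[hg.genome_id])
    return PairComplementarityResult(
        phage_id=pg.genome_id,
        host_id=hg.genome_id,
        d_c=profile.base_distance,
        gc_phage=genome_io.gc_content([pg]),
        gc_host=genome_io.gc_content([hg]),
        profile=profile,
        aa_impacts=aggregate_by_amino_acid(profile),
        family=family,
    )


def batch_pair_analysis(
    pairs: list[tuple],
) -> tuple[list[PairComplementarityResult], list[tuple[str, str]]]:
    """Analyse many phage-host pairs; failures are reported, never dropped.

    Each pair is (phage, host, family) where phage/host are GenBank paths or
    pre-parsed (GenomeRecord, CdsFeatures). Returns (results, failure rows
    as (pair label, reason)).
    """
    results: list[PairComplementarityResult] = []
    failures: list[tuple[str, str]] = []
    if not pairs:
        import warnings

        warnings.warn("batch_pair_analysis: empty pair list")
        return results, failures
    for i, (phage, host, family) in enumerate(pairs):
        label = f"pair_{i}"
        try:
            results.append(pair_analysis(phage, host, family))
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append((label, str(exc)))
    return results, failures
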