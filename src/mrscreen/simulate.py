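"""Synthetic probe-level data with a planted ground truth.

Emulates PM/MM probe-pair intensities for four cell populations (source,
source-origin, target, target-stem) with biological replicates.  A small
number of planted regulator genes are "on" exactly in target and
target-stem; for every other of the 2^4 on/off patterns a block of decoy
genes is planted, so each elimination path of the screen is exercised.
Remaining genes are constitutively off background.

Intensity model, per probe pair and sample::

    PM = bg + signal * affinity * noise_pm
    MM = bg + mm_leak * signal * affinity * noise_mm

where ``bg ~ N(background_mu, background_sigma^2)`` is drawn once per
pair and shared by PM and MM (the two probes of a pair are physically
adjacent on the array), ``signal`` is ``signal_scale`` for an off gene
and ``signal_scale * 2**effect_log2`` for an on gene, ``affinity`` is a
per-probe log-normal sequence effect (median 1) shared across samples,
and ``noise_*`` are independent log-normal multiplicative noises with
coefficient of variation ``noise_cv``.

All draws come from one ``numpy`` generator seeded from ``seed``, in a
fixed documented order (probe-set counts, affinities, TF decoy tags,
unannotated tags, then per-sample background / PM noise / MM noise), so a
given configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .containers import (
    ROLES,
    AnnotationSet,
    GeneMap,
    GroupDesign,
    ProbeLevelDataset,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "TARGET_PATTERN",
    "simulate_dataset",
    "expected_screen_truth",
    "sample_normexp",
]

#: On/off pattern of a master regulator over (source, source_origin,
#: target, target_stem): off in both source populations, on in target and
#: target-stem.
TARGET_PATTERN: Tuple[bool, bool, bool, bool] = (False, False, True, True)

#: Group labels used for the four roles in generated designs.
ROLE_GROUPS: Dict[str, str] = {
    "source": "DFAT",
    "source_origin": "AC",
    "target": "HC",
    "target_stem": "RLSC",
}


@dataclass
class SimConfig:
    """Generator configuration; defaults define the reference conditions.

    ``probesets_per_gene`` maps probe-set count to probability.
    ``background_mu``/``background_sigma`` are the per-pair optical/cross-
    hybridization background (intensity units); ``signal_scale`` is the
    true hybridization signal of an off gene, elevated ``2**effect_log2``-
    fold for on genes.  ``mm_leak`` is the fraction of specific signal
    reaching the mismatch probe.  ``tf_decoy_fraction`` of the decoy genes
    are tagged as transcription factors alongside all regulators;
    ``unannotated_fraction`` of background probe sets are left out of the
    gene map.
    """

    n_genes: int = 2000
    probesets_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.9, 2: 0.1}
    )
    pairs_per_probeset: int = 11
    replicates_per_group: int = 3
    n_regulators: int = 3
    n_confounders_per_pattern: int = 20
    effect_log2: float = 4.0
    background_mu: float = 200.0
    background_sigma: float = 4.0
    signal_scale: float = 4.0
    mm_leak: float = 0.05
    noise_cv: float = 0.1
    affinity_log_sd: float = 0.25
    tf_decoy_fraction: float = 0.5
    unannotated_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated constraint."""
        problems: List[str] = []
        n_decoys = (2 ** len(ROLES) - 1) * self.n_confounders_per_pattern
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.n_regulators < 0:
            problems.append("n_regulators must be >= 0")
        if self.n_regulators + n_decoys > self.n_genes:
            problems.append(
                f"n_regulators + decoys ({self.n_regulators} + {n_decoys}) "
                f"exceeds n_genes ({self.n_genes})"
            )
        probs = dict(self.probesets_per_gene)
        if not probs or any(k < 1 for k in probs) or any(p < 0 for p in probs.values()):
            problems.append("probesets_per_gene must map counts >=1 to probs >=0")
        elif abs(sum(probs.values()) - 1.0) > 1e-9:
            problems.append("probesets_per_gene probabilities must sum to 1")
        if self.pairs_per_probeset < 1:
            problems.append("pairs_per_probeset must be >= 1")
        if self.replicates_per_group < 1:
            problems.append("replicates_per_group must be >= 1")
        for name in ("background_mu", "signal_scale"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if self.background_sigma < 0:
            problems.append("background_sigma must be >= 0")
        if not (0.0 <= self.mm_leak < 1.0):
            problems.append("mm_leak must lie in [0, 1)")
        for name in ("noise_cv", "affinity_log_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("tf_decoy_fraction", "unannotated_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                problems.append(f"{name} must lie in [0, 1]")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Planted ground truth of a simulated dataset."""

    regulators: List[str]
    pattern_of: Dict[str, Tuple[bool, bool, bool, bool]]
    tf_genes: frozenset


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def sample_normexp(
    n: int, mu: float, sigma: float, alpha_inv: float, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` values from the normal + exponential convolution.

    Convenience sampler for calibrating/validating the background model:
    N(mu, sigma^2) background plus Exp(mean alpha_inv) signal, truncated
    to stay positive.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, n) + rng.exponential(alpha_inv, n)
    return np.maximum(x, np.finfo(np.float64).tiny)


def _gene_table(config: SimConfig) -> Tuple[List[str], List[Tuple[bool, ...]]]:
    """Fixed gene order: regulators, decoys per pattern, background."""
    names: List[str] = []
    patterns: List[Tuple[bool, ...]] = []
    for i in range(config.n_regulators):
        names.append(f"Reg{i + 1:02d}")
        patterns.append(TARGET_PATTERN)
    all_patterns = sorted(product((False, True), repeat=len(ROLES)))
    for pat in all_patterns:
        if pat == TARGET_PATTERN:
            continue
        code = "".join("1" if on else "0" for on in pat)
        for j in range(config.n_confounders_per_pattern):
            names.append(f"Dcy{code}n{j + 1:02d}")
            patterns.append(pat)
    off = tuple(False for _ in ROLES)
    n_background = config.n_genes - len(names)
    for j in range(n_background):
        names.append(f"Bgn{j + 1:05d}")
        patterns.append(off)
    return names, patterns


def simulate_dataset(
    config: SimConfig,
) -> Tuple[ProbeLevelDataset, GroupDesign, GeneMap, AnnotationSet, SimTruth]:
    """Generate a full synthetic study: data, design, annotation, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, patterns = _gene_table(config)
    n_genes = len(names)

    # draw 1: probe sets per gene
    counts = sorted(config.probesets_per_gene)
    probs = np.array([config.probesets_per_gene[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    ps_per_gene = rng.choice(counts, size=n_genes, p=probs)

    probeset_gene: List[int] = []  # gene index per probe set
    probeset_ids: List[str] = []
    idx = 0
    for g in range(n_genes):
        for _ in range(int(ps_per_gene[g])):
            idx += 1
            probeset_ids.append(f"ps{idx:05d}")
            probeset_gene.append(g)
    n_probesets = len(probeset_ids)
    n_pairs = n_probesets * config.pairs_per_probeset

    # draw 2: per-probe affinities (log-normal, median 1, shared across samples)
    affinity = rng.lognormal(mean=0.0, sigma=config.affinity_log_sd, size=n_pairs)

    # draw 3: TF tags for decoys
    is_decoy = np.array([n.startswith("Dcy") for n in names])
    decoy_idx = np.flatnonzero(is_decoy)
    decoy_tf = rng.random(decoy_idx.size) < config.tf_decoy_fraction
    tf_genes = {names[i] for i in range(config.n_regulators)}
    tf_genes |= {names[g] for g, tag in zip(decoy_idx, decoy_tf) if tag}

    # draw 4: unannotated background probe sets
    is_background_ps = np.array(
        [names[g].startswith("Bgn") for g in probeset_gene]
    )
    unannot = rng.random(n_probesets) < config.unannotated_fraction
    unannot &= is_background_ps

    # samples in role order, replicates within role
    samples: List[str] = []
    sample_role: List[str] = []
    assignments: Dict[str, str] = {}
    for role in ROLES:
        group = ROLE_GROUPS[role]
        for r in range(config.replicates_per_group):
            name = f"{group}_{r + 1}"
            samples.append(name)
            sample_role.append(role)
            assignments[name] = group

    gene_of_pair = np.repeat(probeset_gene, config.pairs_per_probeset)
    aff = affinity
    on_matrix = np.array(patterns)  # (n_genes, 4) over ROLES order
    role_index = {role: k for k, role in enumerate(ROLES)}
    signal_on = config.signal_scale * 2.0**config.effect_log2
    floor = np.finfo(np.float64).tiny

    pm = np.empty((n_pairs, len(samples)))
    mm = np.empty((n_pairs, len(samples)))
    # draw 5: per sample, background then PM noise then MM noise
    for j, role in enumerate(sample_role):
        on = on_matrix[gene_of_pair, role_index[role]]
        signal = np.where(on, signal_on, config.signal_scale)
        bg = rng.normal(config.background_mu, config.background_sigma, n_pairs)
        noise_pm = _lognormal_noise(rng, config.noise_cv, n_pairs)
        noise_mm = _lognormal_noise(rng, config.noise_cv, n_pairs)
        pm[:, j] = bg + signal * aff * noise_pm
        mm[:, j] = bg + config.mm_leak * signal * aff * noise_mm
    np.maximum(pm, floor, out=pm)
    np.maximum(mm, floor, out=mm)

    dataset = ProbeLevelDataset(
        samples=samples,
        probeset_ids=np.repeat(
            np.asarray(probeset_ids, dtype=object), config.pairs_per_probeset
        ),
        pair_index=np.tile(
            np.arange(config.pairs_per_probeset), n_probesets
        ),
        pm=pm,
        mm=mm,
    )
    design = GroupDesign(assignments=assignments, roles=dict(ROLE_GROUPS))
    gene_map = GeneMap(
        entries={
            ps: names[g]
            for ps, g, drop in zip(probeset_ids, probeset_gene, unannot)
            if not drop
        }
    )
    tf_set = AnnotationSet(class_id="TF", genes=frozenset(tf_genes))
    truth = SimTruth(
        regulators=[names[i] for i in range(config.n_regulators)],
        pattern_of=dict(zip(names, patterns)),
        tf_genes=tf_set.genes,
    )
    return dataset, design, gene_map, tf_set, truth


def expected_screen_truth(truth: SimTruth, tf: AnnotationSet) -> frozenset:
    """Gene set an ideal, noise-free screen must output.

    Genes whose on/off pattern is exactly (off, off, on, on) over
    (source, source_origin, target, target_stem), intersected with the
    transcription-factor class.
    """
    with_pattern = {
        g for g, pat in truth.pattern_of.items() if tuple(pat) == TARGET_PATTERN
    }
    return frozenset(with_pattern & set(tf.genes))
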