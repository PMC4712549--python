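"""Seedable generators for every input the pipeline consumes.

The LDA generator emulates the study design: two pooled knockdown and two
pooled control samples, two 384-well plates (A/B) jointly covering the
assay panel, a subset of assays measured in duplicate, planted log2
effects applied to the knockdown arm, a low-expression stratum near or
beyond the detection limit, and on/off features whose silent arm falls
past the instrument's maximum cycle and is emitted as "Undetermined".
Every generator is a pure function of its arguments including the seed,
and ships a ground-truth manifest for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleSheet
from .normalize import ExpressionMatrix

__all__ = [
    "SimulatedLda",
    "simulate_lda",
    "SimulatedMti",
    "simulate_mti",
    "SimulatedArray",
    "simulate_expression_array",
]


@dataclass
class SimulatedLda:
    ct: CtMatrix
    samples: SampleSheet
    truth: pd.DataFrame


def simulate_lda(
    n_features: int = 664,
    n_duplicates: int = 72,
    n_per_group: int = 2,
    frac_de: float = 21 / 664,
    frac_onoff: float = 6 / 664,
    effect_range: tuple[float, float] = (1.5, 4.0),
    noise_sd: float = 0.25,
    baseline_ct_range: tuple[float, float] = (24.0, 33.0),
    frac_low_expression: float = 0.47,
    ct_cutoff: float = 34.5,
    max_cycle: float = 40.0,
    seed: int = 0,
) -> SimulatedLda:
    """Simulate a two-plate TaqMan card run with known ground truth.

    ``frac_de`` is the fraction of features with a planted knockdown effect,
    *including* the ``frac_onoff`` fraction constructed as on/off switches
    (one arm silent).  Defaults mirror the screen's design: 664 distinct
    miRNAs, 72 in duplicate, 2 pooled samples per arm, 15 quantifiable
    effects plus 6 on/off switches, and roughly half the panel expressed
    above the detection limit.
    """
    if not 0 <= frac_onoff <= frac_de <= 1:
        raise ValueError("need 0 <= frac_onoff <= frac_de <= 1")
    if effect_range[0] <= 0 or effect_range[1] < effect_range[0]:
        raise ValueError("effect_range must be a positive interval")
    rng = np.random.default_rng(seed)

    n_de_total = int(round(n_features * frac_de))
    n_onoff = int(round(n_features * frac_onoff))
    n_sig = n_de_total - n_onoff
    n_null = n_features - n_de_total
    n_low = min(int(round(n_features * frac_low_expression)), n_null)

    mirnas = [f"hsa-mir-{i:04d}" for i in range(1, n_features + 1)]
    roles = (["sig"] * n_sig + ["onoff"] * n_onoff
             + ["low"] * n_low + ["null"] * (n_null - n_low))
    roles = list(rng.permutation(roles))

    kd_samples = [f"KD{i+1}" for i in range(n_per_group)]
    ctl_samples = [f"CTL{i+1}" for i in range(n_per_group)]
    samples = SampleSheet(pd.DataFrame({
        "sample_id": kd_samples + ctl_samples,
        "group": ["knockdown"] * n_per_group + ["control"] * n_per_group,
        "label": [f"si-fusion-{i+1}" for i in range(n_per_group)]
                 + [f"si-ctrl-{i+1}" for i in range(n_per_group)],
    }))

    dup_features = set(rng.choice(n_features, size=n_duplicates, replace=False)) \
        if n_duplicates else set()

    lo, hi = baseline_ct_range
    records = []
    truth_rows = []
    for idx, (mirna, role) in enumerate(zip(mirnas, roles)):
        if role == "sig":
            baseline = rng.uniform(lo, min(hi, ct_cutoff - effect_range[1] - 1.0))
            effect = rng.uniform(*effect_range) * rng.choice([-1.0, 1.0])
            kd_latent = baseline - effect  # up in knockdown <=> lower CT
            ctl_latent = baseline
            is_de, is_onoff, direction = True, False, ""
            true_lfc = effect
        elif role == "onoff":
            baseline = rng.uniform(26.0, 30.0)
            silent = max_cycle + 2.0  # beyond run length: emitted undetermined
            on_in_kd = bool(rng.integers(2))
            kd_latent = baseline if on_in_kd else silent
            ctl_latent = silent if on_in_kd else baseline
            direction = "on_in_knockdown" if on_in_kd else "off_in_knockdown"
            is_de, is_onoff = True, True
            true_lfc = (ct_cutoff - baseline) if on_in_kd else (baseline - ct_cutoff)
        elif role == "low":
            baseline = rng.uniform(ct_cutoff + 0.5, max_cycle + 3.0)
            kd_latent = ctl_latent = baseline
            is_de, is_onoff, direction, true_lfc = False, False, "", 0.0
        else:
            baseline = rng.uniform(lo, hi)
            kd_latent = ctl_latent = baseline
            is_de, is_onoff, direction, true_lfc = False, False, "", 0.0

        dup_group = mirna if idx in dup_features else ""
        copies = [(f"{mirna}", "A" if idx % 2 == 0 else "B")]
        if dup_group:
            copies = [(f"{mirna}#1", copies[0][1]),
                      (f"{mirna}#2", "B" if copies[0][1] == "A" else "A")]
        for assay_id, plate in copies:
            for sample_id in kd_samples + ctl_samples:
                latent = kd_latent if sample_id in kd_samples else ctl_latent
                ctv = latent + rng.normal(0.0, noise_sd)
                records.append({
                    "assay_id": assay_id, "mirna_name": mirna, "plate": plate,
                    "sample_id": sample_id,
                    "ct": np.nan if ctv > max_cycle else max(ctv, 0.0),
                    "duplicate_group": dup_group,
                })
        truth_rows.append({
            "feature_id": mirna, "true_log2fc": true_lfc, "is_de": is_de,
            "is_onoff": is_onoff, "onoff_direction": direction,
            "duplicate_group": dup_group, "noise_sd": noise_sd, "seed": seed,
        })

    ct = CtMatrix(pd.DataFrame(records), max_cycle=max_cycle)
    truth = pd.DataFrame(truth_rows).set_index("feature_id")
    return SimulatedLda(ct, samples, truth)


@dataclass
class SimulatedMti:
    mti: pd.DataFrame
    gene_terms: pd.DataFrame
    directions: pd.Series
    expressed_genes: list[str]


def simulate_mti(
    n_mirnas: int = 21,
    n_genes: int = 300,
    n_terms: int = 12,
    score_range: tuple[float, float] = (-0.6, -0.05),
    targets_per_mirna: int = 25,
    n_curated: int = 60,
    frac_weak_evidence: float = 0.6,
    frac_expressed: float = 0.8,
    seed: int = 0,
) -> SimulatedMti:
    """Random bipartite MTI table with context+ scores, terms and directions."""
    if not (-1.0 < score_range[0] <= score_range[1] < 0.0):
        raise ValueError("score_range must be a negative interval within (-1, 0)")
    rng = np.random.default_rng(seed)
    mirnas = [f"hsa-mir-s{i:03d}" for i in range(1, n_mirnas + 1)]
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    rows = []
    for m in mirnas:
        k = min(targets_per_mirna, n_genes)
        for g_idx in rng.choice(n_genes, size=k, replace=False):
            rows.append({
                "mirna_id": m, "gene_id": genes[g_idx], "source": "predicted",
                "evidence": "none",
                "context_score": rng.uniform(score_range[0], score_range[1]),
            })
    for _ in range(n_curated):
        rows.append({
            "mirna_id": mirnas[rng.integers(n_mirnas)],
            "gene_id": genes[rng.integers(n_genes)],
            "source": "curated",
            "evidence": "weak" if rng.random() < frac_weak_evidence else "strong",
            "context_score": np.nan,
        })
    mti = pd.DataFrame(rows).drop_duplicates(
        subset=["mirna_id", "gene_id", "source"]).reset_index(drop=True)
    term_rows = []
    for t in range(1, n_terms + 1):
        size = int(rng.integers(8, max(9, n_genes // 6)))
        for g_idx in rng.choice(n_genes, size=size, replace=False):
            term_rows.append({"gene_id": genes[g_idx], "term_id": f"T{t:03d}",
                              "term_name": f"process {t:03d}"})
    gene_terms = pd.DataFrame(term_rows).drop_duplicates().reset_index(drop=True)
    directions = pd.Series(
        rng.choice(["up_in_knockdown", "down_in_knockdown"], size=n_mirnas),
        index=mirnas,
    )
    n_expr = int(round(frac_expressed * n_genes))
    expressed = [genes[i] for i in sorted(rng.choice(n_genes, size=n_expr, replace=False))]
    return SimulatedMti(mti, gene_terms, directions, expressed)


@dataclass
class SimulatedArray:
    expression: ExpressionMatrix
    probe_to_gene: pd.Series
    truth: pd.DataFrame


def simulate_expression_array(
    n_probes: int = 1000,
    n_genes: int = 400,
    n_per_group: int = 2,
    frac_de: float = 0.1,
    effect_range: tuple[float, float] = (1.0, 3.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SimulatedArray:
    """One-color intensity matrix with 1-3 replicate probes per gene.

    Differentially expressed genes receive one common planted effect across
    all of their probes, so the replicate-probe consensus rule is exercised
    end to end.
    """
    if n_probes < n_genes:
        raise ValueError("need n_probes >= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    counts = np.ones(n_genes, dtype=int)
    extra = n_probes - n_genes
    while extra > 0:
        g = int(rng.integers(n_genes))
        if counts[g] < 3:
            counts[g] += 1
            extra -= 1
    n_de = int(round(frac_de * n_genes))
    de_genes = set(rng.choice(n_genes, size=n_de, replace=False))
    kd = [f"T{i+1}" for i in range(n_per_group)]
    ctl = [f"C{i+1}" for i in range(n_per_group)]
    samples = kd + ctl
    probe_ids, gene_of, rows, truth_rows = [], [], [], []
    for gi, gene in enumerate(genes):
        effect = 0.0
        if gi in de_genes:
            effect = rng.uniform(*effect_range) * rng.choice([-1.0, 1.0])
        base = rng.uniform(6.0, 12.0)
        for rep in range(counts[gi]):
            pid = f"{gene}_p{rep+1}"
            probe_ids.append(pid)
            gene_of.append(gene)
            vals = [base + effect + rng.normal(0, noise_sd) for _ in kd] + \
                   [base + rng.normal(0, noise_sd) for _ in ctl]
            rows.append(vals)
        truth_rows.append({"gene_id": gene, "true_log2fc": effect,
                           "is_de": gi in de_genes, "n_probes": counts[gi],
                           "seed": seed})
    x = ExpressionMatrix(
        pd.DataFrame(rows, index=probe_ids, columns=samples),
        (f"simulate_expression_array(seed={seed})",),
    )
    return SimulatedArray(x, pd.Series(gene_of, index=probe_ids),
                          pd.DataFrame(truth_rows).set_index("gene_id"))
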