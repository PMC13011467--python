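"""Synthetic multi-omics inputs with known ground truth.

Every dataset the pipeline consumes can be generated here, emulating the
study design of a salt-supplementation experiment in a *Streptomyces*-like
bacterium with a linear chromosome:

* LC-MS feature tables — 2 salinity conditions x 3 time points x 3
  biological replicates (plus blank media samples), log-normal feature
  signals, with a chosen subset of features carrying a planted salinity x
  time interaction (one cell of the 2x3 design multiplied by a large
  fold);
* gene models — non-overlapping strand-annotated genes on the linear
  chromosome, writable as GFF3;
* Cappable-seq fragments — per condition x replicate BED-style fragment
  records whose 5' ends pile up at planted TSS positions with small
  Gaussian jitter over a uniform background of spurious ends;
* expression tables — per-gene log2 fold change and adjusted p versus a
  preculture reference for six conditions, with planted DE and
  salt-responsive genes.

All draws stem from a single seed via ``numpy.random.SeedSequence`` child
streams, so each dataset is deterministic and independent of the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import CONDITIONS
from .exceptions import InvalidConfigError

TIME_POINTS_H = (0.5, 48.0, 96.0)
SALINITY_CONDITIONS = ("salt", "no_salt")
TSS_CONDITIONS = ("salt_t1", "salt_t2", "no_salt_t1", "no_salt_t2")
N_REPLICATES = 3
N_BLANKS = 3


@dataclass
class SimConfig:
    """Study-design parameters for all synthetic datasets.

    LC-MS: ``n_features`` features with per-feature baseline drawn around
    ``baseline_log10_mean`` (log10 signal units), replicate coefficient of
    variation ``replicate_cv``, and ``n_planted_diff`` features whose
    signal in one random (salinity, time) cell is multiplied by
    ``planted_interaction_fold`` (>= 100 so planted features clear both
    the 10x prefilter and the 100x gate).

    TSS: ``n_true_tss`` sites on a linear chromosome of
    ``chromosome_length`` nt, each emitting ~``tss_mean_count`` fragment
    ends per replicate (Poisson) jittered by a normal of sd
    ``tss_jitter_sd`` nt, over a uniform background of
    ``background_end_rate`` spurious ends per nt per strand.

    Expression: ``n_genes`` genes with ``n_planted_de`` DE genes of which
    ``n_planted_salt_up`` are salt-responsive.
    """

    seed: int = 0
    n_features: int = 2000
    n_planted_diff: int = 40
    baseline_log10_mean: float = 7.5
    replicate_cv: float = 0.2
    planted_interaction_fold: float = 200.0
    n_genes: int = 300
    chromosome_length: int = 1_000_000
    n_true_tss: int = 200
    tss_mean_count: float = 50.0
    tss_jitter_sd: float = 1.0
    background_end_rate: float = 1e-4
    n_planted_de: int = 60
    n_planted_salt_up: int = 20
    n_conditions: int = 4
    n_replicates: int = N_REPLICATES

    def __post_init__(self):
        if self.n_features <= 0 or self.chromosome_length <= 0:
            raise InvalidConfigError("counts and lengths must be positive")
        if self.n_genes < 0:
            raise InvalidConfigError("n_genes must be non-negative")
        if not (0 <= self.n_planted_diff <= self.n_features):
            raise InvalidConfigError("n_planted_diff out of range")
        if self.n_true_tss < 0 or self.tss_mean_count < 0:
            raise InvalidConfigError("TSS counts must be non-negative")
        if self.tss_jitter_sd < 0 or self.background_end_rate < 0:
            raise InvalidConfigError("jitter and background rate must be non-negative")
        if self.replicate_cv <= 0:
            raise InvalidConfigError("replicate_cv must be positive")
        if self.n_planted_diff and self.planted_interaction_fold < 100:
            raise InvalidConfigError(
                "planted_interaction_fold must be >= 100 (the effect-size gate)"
            )
        if not (0 <= self.n_planted_salt_up <= self.n_planted_de <= self.n_genes):
            raise InvalidConfigError("need salt_up <= de <= n_genes")
        if self.n_conditions != 4 or self.n_replicates != 3:
            raise InvalidConfigError("the study design is fixed at 4 conditions x 3 replicates")

    def _child_rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("lcms", "annotation", "tss", "expression")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class GroundTruth:
    """Planted objects, recoverable from the emitted files alone."""

    differential_feature_ids: frozenset = frozenset()
    de_gene_ids: frozenset = frozenset()
    salt_up_gene_ids: frozenset = frozenset()
    true_tss: tuple = ()  # (position, strand, frozenset of conditions)

    def __post_init__(self):
        if not self.salt_up_gene_ids <= self.de_gene_ids:
            raise InvalidConfigError("salt_up genes must be a subset of DE genes")


def sample_design() -> pd.DataFrame:
    """The complete 2 x 3 x 3 biological design plus blank media samples."""
    rows = []
    for cond in SALINITY_CONDITIONS:
        for t in TIME_POINTS_H:
            for rep in range(1, N_REPLICATES + 1):
                rows.append(
                    {"sample_id": f"{cond}_t{t:g}_r{rep}", "condition": cond,
                     "time_h": t, "replicate": rep, "is_blank": False}
                )
    for b in range(1, N_BLANKS + 1):
        rows.append(
            {"sample_id": f"blank_r{b}", "condition": "blank", "time_h": 0.0,
             "replicate": b, "is_blank": True}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_lcms_dataset(config: SimConfig):
    """Simulate an LC-MS feature table; returns ``(FeatureTable, GroundTruth)``.

    Null features share one log-normal mean across all 18 biological
    samples (CV = ``replicate_cv``); planted features have the mean of one
    (salinity, time) cell multiplied by ``planted_interaction_fold``.
    Blank samples sit at 1/10 of each feature's baseline so default data
    clears the 3x blank filter.
    """
    from .metabolomics import FeatureTable

    rng = config._child_rngs()["lcms"]
    n = config.n_features
    design = sample_design()
    bio = design.index[~design["is_blank"]]
    blanks = design.index[design["is_blank"]]

    feature_ids = [f"F{i + 1:05d}" for i in range(n)]
    base_log10 = rng.normal(config.baseline_log10_mean, 0.5, size=n)
    mz = np.round(rng.uniform(100.0, 1000.0, size=n), 4)
    rt = np.round(rng.uniform(0.5, 8.0, size=n), 3)
    mode = np.where(rng.random(n) < 0.5, "positive", "negative")

    planted_idx = rng.choice(n, size=config.n_planted_diff, replace=False)
    planted_cell = rng.integers(0, 6, size=config.n_planted_diff)

    sigma_ln = np.sqrt(np.log1p(config.replicate_cv**2))
    log_mean = np.log(10.0) * base_log10[:, None] * np.ones((n, len(bio)))
    cell_of_sample = np.array(
        [SALINITY_CONDITIONS.index(design.loc[s, "condition"]) * 3
         + TIME_POINTS_H.index(design.loc[s, "time_h"]) for s in bio]
    )
    for i, cell in zip(planted_idx, planted_cell):
        log_mean[i, cell_of_sample == cell] += np.log(config.planted_interaction_fold)
    noise = rng.normal(0.0, sigma_ln, size=(n, len(bio)))
    signals_bio = np.exp(log_mean - sigma_ln**2 / 2 + noise)

    blank_mean = np.log(10.0) * base_log10[:, None] - np.log(10.0)
    blank_noise = rng.normal(0.0, sigma_ln, size=(n, len(blanks)))
    signals_blank = np.exp(blank_mean - sigma_ln**2 / 2 + blank_noise)

    signals = pd.DataFrame(
        np.hstack([signals_bio, signals_blank]),
        index=pd.Index(feature_ids, name="feature_id"),
        columns=list(bio) + list(blanks),
    )[design.index]
    features = pd.DataFrame(
        {"mz": mz, "rt": rt, "mode": mode},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    truth = GroundTruth(
        differential_feature_ids=frozenset(feature_ids[i] for i in planted_idx)
    )
    return FeatureTable(features=features, signals=signals, samples=design), truth


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping strand-annotated gene models on the linear chromosome.

    Genes are laid out one per equal-width slot (1-based inclusive
    coordinates, sorted by start) so disjointness is guaranteed by
    construction. Raises :class:`InvalidConfigError` when the chromosome
    cannot hold ``n_genes`` genes.
    """
    rng = config._child_rngs()["annotation"]
    n = config.n_genes
    if n == 0:
        return pd.DataFrame(columns=["gene_id", "start", "end", "strand"]).astype(
            {"start": int, "end": int}
        )
    slot = config.chromosome_length // n
    if slot < 300:
        raise InvalidConfigError(
            f"chromosome too short for {n} genes ({slot} nt per gene slot)"
        )
    margin = max(50, slot // 10)
    rows = []
    for i in range(n):
        lo = i * slot + 1
        hi = (i + 1) * slot
        max_len = hi - margin - (lo + margin) + 1
        length = int(rng.integers(min(200, max_len), max_len + 1))
        start = int(rng.integers(lo + margin, hi - margin - length + 2))
        rows.append(
            {"gene_id": f"gene_{i + 1:04d}", "start": start,
             "end": start + length - 1,
             "strand": "+" if rng.random() < 0.5 else "-"}
        )
    return pd.DataFrame(rows)


def generate_tss_reads(config: SimConfig, annotation: pd.DataFrame | None = None):
    """Simulate Cappable-seq fragments; returns ``(fragments, GroundTruth)``.

    ``fragments`` maps (condition, replicate) to a BED-convention
    DataFrame (chrom, start, end, name, score, strand; 0-based
    half-open). Each planted TSS emits, in every condition of its
    condition set and every replicate, Poisson(``tss_mean_count``)
    fragments whose 5' ends are jittered by a rounded normal of sd
    ``tss_jitter_sd`` (clamped to the chromosome); background ends are
    uniform at ``background_end_rate`` per nt per strand.
    """
    rng = config._child_rngs()["tss"]
    L = config.chromosome_length

    # planted sites on a coarse grid => pairwise distance >= 50 nt, so
    # every site maps to a distinct cluster at the 5-nt calling window
    grid = np.arange(100, L - 100, 50)
    if config.n_true_tss > grid.size:
        raise InvalidConfigError("too many TSSs for the chromosome length")
    positions = np.sort(rng.choice(grid, size=config.n_true_tss, replace=False))
    strands = np.where(rng.random(config.n_true_tss) < 0.5, "+", "-")
    cond_sets = []
    for _ in range(config.n_true_tss):
        if rng.random() < 0.4:
            cond_sets.append(frozenset(TSS_CONDITIONS))
        else:
            k = int(rng.integers(1, len(TSS_CONDITIONS)))
            cond_sets.append(frozenset(rng.choice(TSS_CONDITIONS, size=k, replace=False)))

    fragments = {}
    for cond in TSS_CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            rows = []
            read_i = 0
            for pos, strand, cset in zip(positions, strands, cond_sets):
                if cond not in cset:
                    continue
                c = int(rng.poisson(config.tss_mean_count))
                if c == 0:
                    continue
                jitter = np.rint(rng.normal(0.0, config.tss_jitter_sd, size=c)).astype(int)
                ends = np.clip(pos + jitter, 1, L)
                lens = rng.integers(200, 501, size=c)
                for e, ln in zip(ends, lens):
                    if strand == "+":
                        start0 = e - 1
                        end0 = min(start0 + int(ln), L)
                    else:
                        end0 = e
                        start0 = max(0, end0 - int(ln))
                    rows.append((start0, end0, strand))
                    read_i += 1
            n_bg = int(rng.poisson(config.background_end_rate * L * 2))
            bg_pos = rng.integers(1, L + 1, size=n_bg)
            bg_strand = np.where(rng.random(n_bg) < 0.5, "+", "-")
            bg_len = rng.integers(200, 501, size=n_bg)
            for p, s, ln in zip(bg_pos, bg_strand, bg_len):
                if s == "+":
                    start0 = p - 1
                    end0 = min(start0 + int(ln), L)
                else:
                    end0 = p
                    start0 = max(0, end0 - int(ln))
                rows.append((start0, end0, s))
            df = pd.DataFrame(rows, columns=["start", "end", "strand"])
            df.insert(0, "chrom", "chr")
            df["name"] = [f"read_{cond}_{rep}_{i}" for i in range(len(df))]
            df["score"] = 1
            fragments[(cond, rep)] = df[["chrom", "start", "end", "name", "score", "strand"]]

    truth = GroundTruth(
        true_tss=tuple(
            (int(p), s, cset) for p, s, cset in zip(positions, strands, cond_sets)
        )
    )
    return fragments, truth


def generate_expression_table(config: SimConfig):
    """Simulate a gene x condition lfc/padj table; returns ``(table, GroundTruth)``.

    Planted salt-up genes carry one strong significant lfc in a salt
    column with null-like no-salt cells; other planted DE genes carry the
    same strong lfc in one salt and one no-salt column (DE but not
    salt-responsive); null genes are non-significant everywhere.
    """
    rng = config._child_rngs()["expression"]
    n = config.n_genes
    gene_ids = [f"gene_{i + 1:04d}" for i in range(n)]

    lfc = rng.normal(0.0, 0.2, size=(n, 6))
    padj = rng.uniform(0.05, 1.0, size=(n, 6))

    de_idx = rng.choice(n, size=config.n_planted_de, replace=False)
    up_idx = de_idx[: config.n_planted_salt_up]
    other_idx = de_idx[config.n_planted_salt_up:]

    for i in up_idx:
        col = int(rng.integers(0, 3))  # a salt column
        lfc[i, col] = rng.uniform(2.5, 5.0)
        padj[i, col] = rng.uniform(1e-6, 0.01)
    for i in other_idx:
        v = rng.uniform(2.5, 5.0)
        salt_col = int(rng.integers(0, 3))
        nosalt_col = int(rng.integers(3, 6))
        lfc[i, salt_col] = v
        lfc[i, nosalt_col] = v
        padj[i, salt_col] = rng.uniform(1e-6, 0.01)
        padj[i, nosalt_col] = rng.uniform(1e-6, 0.01)

    data = {}
    for j, cond in enumerate(CONDITIONS):
        data[f"{cond}_lfc"] = np.round(lfc[:, j], 6)
        data[f"{cond}_padj"] = np.round(padj[:, j], 8)
    table = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    truth = GroundTruth(
        de_gene_ids=frozenset(gene_ids[i] for i in de_idx),
        salt_up_gene_ids=frozenset(gene_ids[i] for i in up_idx),
    )
    return table, truth


def generate_annotation_categories(config: SimConfig, n_categories: int = 8):
    """Functional-category and conservation annotation for the gene set.

    Plumbing for the enrichment and conservation-binning stages: every
    gene gets one of ``n_categories`` category labels and a conservation
    fraction in [0, 1].
    """
    rng = config._child_rngs()["expression"].spawn(1)[0]
    gene_ids = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]
    cats = [f"COG_{chr(65 + i)}" for i in range(n_categories)]
    return pd.DataFrame(
        {"gene_id": gene_ids,
         "category": rng.choice(cats, size=config.n_genes),
         "conservation": np.round(rng.uniform(0.0, 1.0, size=config.n_genes), 4)}
    )
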