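"""Synthetic two-group transcriptomes, interaction tables and signature
mixtures with known ground truth.

The transcriptome generator emulates the study design the pipeline targets: a
small two-group cohort (defaults 11 control vs 15 case) of log2 expression
values with

* planted differentially expressed genes (fixed log2 fold change),
* planted lncRNA-mRNA pairs that share a latent per-sample factor (so their
  population Pearson correlation hits a chosen target) and share at least one
  miRNA in the emitted interaction table, and
* three decoy classes that each violate exactly one ceRNA admission
  criterion: correlated but sharing no miRNA, sharing a miRNA but
  uncorrelated, and anti-correlated.

Every gene keeps total within-group standard deviation ``noise_sd``: a pair
member is ``sqrt(|r|)*noise_sd*f + sqrt(1-|r|)*noise_sd*eps`` with a shared
standard-normal factor ``f``, which gives population correlation exactly
``r`` inside each group (the latent-factor closed form
``r = lambda^2 / (lambda^2 + sigma^2)`` with ``lambda^2 = |r| noise_sd^2``).

Correlations downstream are computed on pooled samples, where group mean
shifts add covariance of their own. Planted pairs (and correlated-no-miRNA
decoys) are shifted up in cases like the biomarker pairs they emulate, which
only raises their pooled correlation; the uncorrelated and anti-correlated
decoy classes get opposite-direction shifts so the group shift cannot
manufacture a spurious positive pooled correlation for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneCatalog, InteractionTable

DecoyClass = Literal["correlated-no-miRNA", "miRNA-no-correlation", "anti-correlated"]
DECOY_CLASSES: tuple[DecoyClass, ...] = (
    "correlated-no-miRNA",
    "miRNA-no-correlation",
    "anti-correlated",
)


@dataclass(frozen=True)
class PlantedPair:
    lncrna: str
    mrna: str
    target_r: float
    shared_mirnas: tuple[str, ...]


@dataclass(frozen=True)
class DecoyPair:
    lncrna: str
    mrna: str
    decoy_class: DecoyClass
    shared_mirnas: tuple[str, ...]  # empty for correlated-no-miRNA


@dataclass
class SyntheticTruth:
    """All planted parameters of a synthetic dataset."""

    de_genes: dict[str, float]  # gene -> planted log2 fold change (case - control)
    planted_pairs: list[PlantedPair]
    decoy_pairs: list[DecoyPair]
    true_fractions: pd.DataFrame | None = None


@dataclass(frozen=True)
class TranscriptomeConfig:
    """Distribution parameters of the synthetic transcriptome.

    Defaults mirror the two-group microarray design the pipeline is built
    for, scaled so a full pipeline run takes seconds: ~1,000 genes of which
    ~100 are lncRNAs, 10 planted ceRNA pairs, 10 decoys per class, planted
    |log2FC| = 2 on a noise sd of 0.5.
    """

    base_mean: float = 6.0       # mean of per-gene baseline log2 expression
    base_sd: float = 2.0         # between-gene spread of baselines
    noise_sd: float = 0.5        # within-group per-gene sd on the log2 scale
    de_lfc: float = 2.0          # |log2FC| planted on background DE genes
    n_de_up: int = 30            # background DE genes shifted up in cases
    n_de_down: int = 30          # background DE genes shifted down in cases
    pair_r: float = 0.95         # target Pearson r of planted pairs
    pair_lfc: float = 2.0        # log2FC planted on pair/decoy members (0 disables)
    n_pairs: int = 10
    n_decoys_per_class: int = 10
    mirnas_per_pair: int = 3     # shared miRNAs given to each planted/decoy pair
    immune_background_frac: float = 0.15  # immune flag rate among other mRNAs
    n_background_edges: int = 300         # random decoy interaction edges


@dataclass
class _PairSpec:
    """Internal: one latent factor shared by two genes."""

    lncrna: str
    mrna: str
    r: float            # signed target correlation within groups
    lnc_lfc: float
    mrna_lfc: float


@dataclass
class TranscriptomeSimulation:
    """Result bundle; unpacks as (expr, catalog, interactions, truth).

    ``resample`` draws an independent cohort (e.g. a validation dataset)
    from the same planted truth.
    """

    expr: ExpressionMatrix
    catalog: GeneCatalog
    interactions: InteractionTable
    truth: SyntheticTruth
    _baselines: pd.Series = field(repr=False, default=None)
    _pair_specs: list[_PairSpec] = field(repr=False, default_factory=list)
    _config: TranscriptomeConfig = field(repr=False, default=None)

    def __iter__(self) -> Iterator:
        return iter((self.expr, self.catalog, self.interactions, self.truth))

    def resample(self, n_control: int, n_case: int, seed: int) -> ExpressionMatrix:
        """Draw a new cohort with identical planted structure."""
        rng = np.random.default_rng(seed)
        return _draw_cohort(
            self._baselines, self.truth.de_genes, self._pair_specs,
            self._config, n_control, n_case, rng,
        )


def _draw_cohort(
    baselines: pd.Series,
    de_genes: dict[str, float],
    pair_specs: list[_PairSpec],
    config: TranscriptomeConfig,
    n_control: int,
    n_case: int,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    genes = list(baselines.index)
    n = n_control + n_case
    samples = [f"C{i+1:02d}" for i in range(n_control)] + [
        f"P{i+1:02d}" for i in range(n_case)
    ]
    case_ind = np.r_[np.zeros(n_control), np.ones(n_case)]
    values = np.tile(baselines.to_numpy()[:, None], (1, n))
    lfc = np.array([de_genes.get(g, 0.0) for g in genes])
    values += lfc[:, None] * case_ind[None, :]

    gene_pos = {g: i for i, g in enumerate(genes)}
    in_pair = set()
    for spec in pair_specs:
        in_pair.update((spec.lncrna, spec.mrna))
        factor = rng.standard_normal(n)
        lam = np.sqrt(abs(spec.r)) * config.noise_sd
        resid = np.sqrt(1.0 - abs(spec.r)) * config.noise_sd
        sign_m = np.sign(spec.r) if spec.r != 0 else 0.0
        values[gene_pos[spec.lncrna]] += lam * factor + resid * rng.standard_normal(n)
        values[gene_pos[spec.mrna]] += (
            sign_m * lam * factor + resid * rng.standard_normal(n)
        )
    free = np.array([g not in in_pair for g in genes])
    values[free] += config.noise_sd * rng.standard_normal((int(free.sum()), n))

    groups = pd.Series(
        ["control"] * n_control + ["case"] * n_case, index=samples, dtype=object
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
        scale="log2",
    )


def simulate_transcriptome(
    n_control: int = 11,
    n_case: int = 15,
    n_genes: int = 1000,
    n_lncrna: int = 100,
    config: TranscriptomeConfig | None = None,
    seed: int = 0,
) -> TranscriptomeSimulation:
    """Generate a two-group expression matrix with planted ceRNA structure.

    Returns a :class:`TranscriptomeSimulation`, which unpacks as
    ``(ExpressionMatrix, GeneCatalog, InteractionTable, SyntheticTruth)``.
    Identical arguments and seed give bit-identical outputs.
    """
    config = config or TranscriptomeConfig()
    if n_control < 3 or n_case < 3:
        raise ValueError("need at least 3 samples per group")
    if not (0.0 < config.pair_r <= 1.0):
        raise ValueError(f"target pair correlation must be in (0, 1], got {config.pair_r}")
    if config.pair_r >= 1.0 and config.noise_sd > 0:
        # r = 1 with nonzero residual noise is unreachable by construction
        raise ValueError("target r = 1 is infeasible with nonzero noise_sd")
    n_mrna = n_genes - n_lncrna
    n_needed = config.n_pairs + 3 * config.n_decoys_per_class
    if n_needed > n_lncrna or n_needed > n_mrna:
        raise ValueError(
            f"{n_needed} planted/decoy pairs need as many lncRNAs and mRNAs "
            f"(have {n_lncrna} lncRNAs, {n_mrna} mRNAs)"
        )

    rng = np.random.default_rng(seed)
    lnc_names = [f"LNC{i+1:04d}" for i in range(n_lncrna)]
    mrna_names = [f"G{i+1:04d}" for i in range(n_mrna)]
    genes = lnc_names + mrna_names

    # assign pair roles: distinct lncRNA and distinct immune mRNA per pair
    lnc_pool = list(rng.permutation(lnc_names))
    mrna_pool = list(rng.permutation(mrna_names))
    take = lambda pool, k: [pool.pop() for _ in range(k)]

    pair_specs: list[_PairSpec] = []
    planted: list[PlantedPair] = []
    decoys: list[DecoyPair] = []
    edges: set[tuple[str, str]] = set()
    mir_counter = 0

    def fresh_mirnas(k: int) -> tuple[str, ...]:
        nonlocal mir_counter
        out = tuple(f"miR-{mir_counter + i + 1}" for i in range(k))
        mir_counter += k
        return out

    for lnc, mrna in zip(take(lnc_pool, config.n_pairs), take(mrna_pool, config.n_pairs)):
        shared = fresh_mirnas(config.mirnas_per_pair)
        edges.update((m, lnc) for m in shared)
        edges.update((m, mrna) for m in shared)
        planted.append(PlantedPair(lnc, mrna, config.pair_r, shared))
        pair_specs.append(
            _PairSpec(lnc, mrna, config.pair_r, config.pair_lfc, config.pair_lfc)
        )

    for cls in DECOY_CLASSES:
        for lnc, mrna in zip(
            take(lnc_pool, config.n_decoys_per_class),
            take(mrna_pool, config.n_decoys_per_class),
        ):
            if cls == "correlated-no-miRNA":
                shared: tuple[str, ...] = ()
                pair_specs.append(
                    _PairSpec(lnc, mrna, config.pair_r, config.pair_lfc, config.pair_lfc)
                )
            elif cls == "miRNA-no-correlation":
                shared = fresh_mirnas(config.mirnas_per_pair)
                pair_specs.append(
                    _PairSpec(lnc, mrna, 0.0, config.pair_lfc, -config.pair_lfc)
                )
            else:  # anti-correlated
                shared = fresh_mirnas(config.mirnas_per_pair)
                pair_specs.append(
                    _PairSpec(lnc, mrna, -config.pair_r, config.pair_lfc, -config.pair_lfc)
                )
            edges.update((m, lnc) for m in shared)
            edges.update((m, mrna) for m in shared)
            decoys.append(DecoyPair(lnc, mrna, cls, shared))

    # random background edges; must never create sharing for no-miRNA decoys
    no_mir_members = {
        frozenset((d.lncrna, d.mrna)) for d in decoys
        if d.decoy_class == "correlated-no-miRNA"
    }
    bg_mirs = [f"miR-bg{i+1}" for i in range(max(1, config.n_background_edges // 5))]
    mir_targets: dict[str, set[str]] = {m: set() for m in bg_mirs}
    added = 0
    while added < config.n_background_edges:
        m = bg_mirs[int(rng.integers(len(bg_mirs)))]
        g = genes[int(rng.integers(n_genes))]
        if any(
            len((mir_targets[m] | {g}) & members) == 2 for members in no_mir_members
        ):
            continue
        if g not in mir_targets[m]:
            mir_targets[m].add(g)
            edges.add((m, g))
            added += 1

    # planted background DE genes, disjoint from pair members
    de_genes: dict[str, float] = {}
    for spec in pair_specs:
        de_genes[spec.lncrna] = spec.lnc_lfc
        de_genes[spec.mrna] = spec.mrna_lfc
    de_genes = {g: v for g, v in de_genes.items() if v != 0.0}
    free_mrnas = [g for g in mrna_pool]
    free_lncs = [g for g in lnc_pool]
    background = list(rng.permutation(free_mrnas + free_lncs))
    for g in background[: config.n_de_up]:
        de_genes[g] = config.de_lfc
    for g in background[config.n_de_up : config.n_de_up + config.n_de_down]:
        de_genes[g] = -config.de_lfc

    # catalog: every pair/decoy mRNA is immune; background mRNAs at a base rate
    pair_mrnas = {s.mrna for s in pair_specs}
    immune = set(pair_mrnas)
    for g in mrna_names:
        if g not in immune and rng.random() < config.immune_background_frac:
            immune.add(g)
    catalog = GeneCatalog(
        table=pd.DataFrame(
            {
                "biotype": ["lncRNA"] * n_lncrna + ["mRNA"] * n_mrna,
                "is_immune": [g in immune and g not in lnc_names for g in genes],
            },
            index=genes,
        )
    )

    baselines = pd.Series(
        config.base_mean + config.base_sd * rng.standard_normal(n_genes), index=genes
    )
    expr = _draw_cohort(baselines, de_genes, pair_specs, config, n_control, n_case, rng)
    truth = SyntheticTruth(de_genes=de_genes, planted_pairs=planted, decoy_pairs=decoys)
    return TranscriptomeSimulation(
        expr=expr,
        catalog=catalog,
        interactions=InteractionTable(edges=frozenset(edges)),
        truth=truth,
        _baselines=baselines,
        _pair_specs=pair_specs,
        _config=config,
    )


# ---------------------------------------------------------------------------
# Signature mixtures
# ---------------------------------------------------------------------------


def synthetic_signature(
    n_types: int = 5, n_markers_per_type: int = 12, seed: int = 0
) -> pd.DataFrame:
    """A small synthetic marker-gene signature matrix (genes x cell types).

    Each cell type over-expresses its own marker block roughly eight-fold
    over a shared log-normal baseline, mimicking the structure (not the
    content) of published leukocyte signatures.
    """
    rng = np.random.default_rng(seed)
    n_markers = n_types * n_markers_per_type
    genes = [f"M{i+1:03d}" for i in range(n_markers)]
    types = [f"CT{i+1}" for i in range(n_types)]
    base = np.exp(rng.normal(np.log(20.0), 0.5, size=(n_markers, n_types)))
    for t in range(n_types):
        block = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        base[block, t] *= 8.0
    return pd.DataFrame(base, index=genes, columns=types)


def simulate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    noise_sd: float = 5.0,
    seed: int = 0,
    concentration: float = 1.0,
    fractions: pd.DataFrame | np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Linear-scale bulk mixtures of signature columns with known fractions.

    Fractions are drawn from a symmetric Dirichlet unless supplied. Each
    sample is ``signature @ fractions + N(0, noise_sd)`` truncated at zero.
    Returns the (ungrouped, linear-scale) mixture matrix and the true
    fraction table (samples x cell types, rows summing to 1).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if signature.shape[1] < 2:
        raise ValueError("signature needs at least 2 cell types")
    if signature.index.has_duplicates:
        raise ValueError("signature marker genes must be distinct")
    rng = np.random.default_rng(seed)
    types = list(signature.columns)
    samples = [f"S{i+1:03d}" for i in range(n_samples)]
    if fractions is None:
        frac = rng.dirichlet(np.full(len(types), concentration), size=n_samples)
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.shape != (n_samples, len(types)):
            raise ValueError(
                f"fractions must be {n_samples} x {len(types)}, got {frac.shape}"
            )
        if (frac < 0).any():
            raise ValueError("fractions must be non-negative")
        frac = frac / frac.sum(axis=1, keepdims=True)
    mix = signature.to_numpy() @ frac.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, None)
    expr = ExpressionMatrix(
        values=pd.DataFrame(mix, index=signature.index, columns=samples),
        groups=None,
        scale="linear",
    )
    frac_table = pd.DataFrame(frac, index=samples, columns=types)
    return expr, frac_table
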