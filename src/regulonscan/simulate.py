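"""Seed-reproducible synthetic inputs with planted regulon structure.

Two entry points:

:func:`generate_dataset`
    Samples a full set of pipeline inputs — expression matrix, DE table,
    regulon database, ortholog map, pathway collection and TF universe —
    from a :class:`SyntheticConfig`.  Each planted TF's regulon enters
    the upregulated set with a configurable odds multiplier ``theta``
    (``theta=1`` is the null), and targets share a latent expression
    factor with their TF at loading ``lambda``, so both the enrichment
    and the correlation stages have known ground truth.

:func:`table1_fixture`
    A deterministic, count-faithful reconstruction of a published
    two-species TF-enrichment table: synthetic gene symbols arranged so
    that every regulon's (expressed, upregulated) overlap counts equal
    the printed ones in both species, including the overlap structure
    between the two dominant regulons, together with an ortholog map
    under which transferring the human regulon database reproduces the
    zebrafish one exactly.

The default configuration mirrors a case-control bulk RNA-seq design of
12 affected and 10 control cortical samples over a ~17,000-gene expressed
universe with 269 upregulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DEGene,
    DETable,
    DomainError,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    Regulon,
    RegulonDB,
)

__all__ = [
    "TFSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "Table1Fixture",
    "table1_fixture",
    "DEFAULT_SEED",
]

#: default documentation seed
DEFAULT_SEED = 20210330


@dataclass
class TFSpec:
    """One planted transcription factor.

    ``theta`` is the odds multiplier for a regulon gene to enter the
    upregulated set relative to a background gene; ``theta=1`` plants
    nothing (null).
    """

    tf_id: str
    regulon_size: int
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise DomainError("theta must be > 0")
        if self.regulon_size < 1:
            raise DomainError("regulon_size must be >= 1")


@dataclass
class SyntheticConfig:
    """Parameters of the planted-regulon generator (defaults = study scale)."""

    seed: int = DEFAULT_SEED
    n_genes: int = 17_000
    n_up: int = 269
    tf_list: list[TFSpec] = field(
        default_factory=lambda: [TFSpec("TF1", regulon_size=600, theta=6.0)]
    )
    n_case: int = 12
    n_control: int = 10
    latent_loading: float = 0.9
    noise_sd: float = 1.0
    ortholog_retention: float = 0.7
    homolog_multiplicity: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1), P(2), P(3)
    n_pathways: int = 50
    species: str = "human"
    to_species: str = "zebrafish"

    def __post_init__(self) -> None:
        if not (0 < self.n_up < self.n_genes):
            raise DomainError("need 0 < n_up < n_genes")
        if not (0.0 <= self.latent_loading < 1.0):
            raise DomainError("latent_loading must lie in [0, 1)")
        if abs(sum(self.homolog_multiplicity) - 1.0) > 1e-9:
            raise DomainError("homolog_multiplicity must sum to 1")
        if not (0.0 <= self.ortholog_retention <= 1.0):
            raise DomainError("ortholog_retention must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Everything :func:`generate_dataset` produces for one seed."""

    expression: ExpressionMatrix | None
    de_table: DETable
    regulons: RegulonDB
    ortholog_map: OrthologMap
    pathways: GeneSetCollection
    tf_universe: GeneSetCollection
    upregulated_truth: frozenset[str]


def _gene_symbols(n: int, tf_ids: Sequence[str]) -> list[str]:
    """TF ids first, then numbered background symbols, ``n`` in total."""
    if len(tf_ids) >= n:
        raise DomainError("n_genes must exceed the number of planted TFs")
    return list(tf_ids) + [f"G{i:05d}" for i in range(1, n - len(tf_ids) + 1)]


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete synthetic input bundle; bit-reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    tf_ids = [t.tf_id for t in cfg.tf_list]
    genes = _gene_symbols(cfg.n_genes, tf_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    background = genes[len(tf_ids):]

    # (ii) regulons sampled uniformly from the background genes
    regulons: dict[str, Regulon] = {}
    owner = np.full(cfg.n_genes, -1, dtype=np.int64)  # first TF claiming a gene
    for ti, spec in enumerate(cfg.tf_list):
        if spec.regulon_size > len(background):
            raise DomainError(
                f"regulon of {spec.tf_id!r} ({spec.regulon_size}) exceeds the "
                f"{len(background)} available background genes"
            )
        picked = rng.choice(len(background), size=spec.regulon_size, replace=False)
        targets = frozenset(background[j] for j in picked)
        regulons[spec.tf_id] = Regulon(tf_id=spec.tf_id, targets=targets,
                                       species=cfg.species)
        for j in picked:
            gi = j + len(tf_ids)
            if owner[gi] < 0:
                owner[gi] = ti

    # (iii) upregulated set: weighted sampling without replacement via
    # Gumbel top-k; regulon genes (and the TF itself) carry odds theta
    weights = np.ones(cfg.n_genes)
    for ti, spec in enumerate(cfg.tf_list):
        weights[gene_index[spec.tf_id]] = spec.theta
        weights[owner == ti] = spec.theta
    keys = np.log(weights) + rng.gumbel(size=cfg.n_genes)
    up_idx = np.argpartition(-keys, cfg.n_up)[: cfg.n_up]
    is_up = np.zeros(cfg.n_genes, dtype=bool)
    is_up[up_idx] = True
    up_truth = frozenset(genes[i] for i in np.nonzero(is_up)[0])

    # (v) DE statistics assigned by construction
    log2fc = rng.normal(0.0, 0.3, size=cfg.n_genes)
    log2fc[is_up] = np.maximum(rng.normal(1.6, 0.6, size=int(is_up.sum())), 0.25)
    padj = rng.uniform(0.051, 1.0, size=cfg.n_genes)
    padj[is_up] = rng.uniform(1e-6, 0.049, size=int(is_up.sum()))

    # (iv) expression: latent-factor log-normal FPKM
    n_samples = cfg.n_case + cfg.n_control
    expression: ExpressionMatrix | None = None
    mu = rng.normal(3.0, 2.0, size=cfg.n_genes)
    if n_samples > 0:
        lam = cfg.latent_loading
        case_mask = np.zeros(n_samples, dtype=bool)
        case_mask[: cfg.n_case] = True
        z_tf = rng.standard_normal((len(cfg.tf_list), n_samples))
        eps = rng.standard_normal((cfg.n_genes, n_samples))
        logx = np.empty((cfg.n_genes, n_samples))
        for gi in range(cfg.n_genes):
            ti = owner[gi]
            if ti >= 0:
                shared = lam * z_tf[ti] + math.sqrt(1.0 - lam * lam) * eps[gi]
            else:
                shared = eps[gi]
            logx[gi] = mu[gi] + cfg.noise_sd * shared
        for ti, spec in enumerate(cfg.tf_list):
            gi = gene_index[spec.tf_id]
            logx[gi] = mu[gi] + cfg.noise_sd * z_tf[ti]
        logx[np.ix_(is_up, case_mask)] += log2fc[is_up][:, None]
        fpkm = np.power(2.0, logx)
        sample_ids = [f"case{i+1:02d}" for i in range(cfg.n_case)] + [
            f"ctrl{i+1:02d}" for i in range(cfg.n_control)
        ]
        ages = np.round(rng.uniform(2.0, 45.0, size=n_samples), 1)
        values = pd.DataFrame(fpkm.T, index=sample_ids, columns=genes)
        meta = pd.DataFrame(
            {
                "group": ["case"] * cfg.n_case + ["control"] * cfg.n_control,
                "age": ages,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        expression = ExpressionMatrix(values=values, metadata=meta)

    base_mean = np.power(2.0, mu)
    de_genes = [
        DEGene(
            gene_id=genes[i],
            log2fc=float(log2fc[i]),
            padj=float(padj[i]),
            group_means={
                "control": float(base_mean[i]),
                "case": float(base_mean[i] * 2.0 ** (log2fc[i] if is_up[i] else 0.0)),
            },
            tested=True,
        )
        for i in range(cfg.n_genes)
    ]
    de_table = DETable(species=cfg.species, genes=de_genes)

    # (vi) ortholog map: per-gene retention, multiplicity over 1..3
    pairs: set[tuple[str, str]] = set()
    retained = rng.random(cfg.n_genes) < cfg.ortholog_retention
    mult = rng.choice(
        np.arange(1, len(cfg.homolog_multiplicity) + 1),
        size=cfg.n_genes,
        p=np.asarray(cfg.homolog_multiplicity),
    )
    for i, g in enumerate(genes):
        if not retained[i]:
            continue
        for j in range(int(mult[i])):
            pairs.add((g, f"{g.lower()}{'abc'[j]}"))
    ortholog_map = OrthologMap(
        from_species=cfg.species, to_species=cfg.to_species,
        pairs=frozenset(pairs),
    )

    # pathway collection: random sets plus one planted mostly-upregulated set
    up_list = sorted(up_truth)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for pi in range(cfg.n_pathways):
        size = int(rng.integers(20, 101))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        sets[f"PW{pi+1:03d}"] = (
            f"random pathway {pi+1}",
            frozenset(genes[j] for j in members),
        )
    n_plant = min(30, len(up_list))
    others = rng.choice(len(background), size=20, replace=False)
    sets["PW_PLANTED"] = (
        "planted upregulated pathway",
        frozenset(up_list[:n_plant]) | frozenset(background[j] for j in others),
    )
    pathways = GeneSetCollection(sets=sets, kind="pathway")

    # TF universe: planted TFs plus decoy annotated factors
    decoys = rng.choice(len(background), size=min(50, len(background)), replace=False)
    tf_universe = GeneSetCollection(
        sets={
            "GO:0003700": (
                "DNA-binding transcription factor activity",
                frozenset(tf_ids) | frozenset(background[j] for j in decoys),
            )
        },
        kind="TF-universe",
    )

    return SyntheticDataset(
        expression=expression,
        de_table=de_table,
        regulons=RegulonDB(regulons=regulons, species=cfg.species),
        ortholog_map=ortholog_map,
        pathways=pathways,
        tf_universe=tf_universe,
        upregulated_truth=up_truth,
    )


# --------------------------------------------------------------------------
# Count-faithful two-species fixture
# --------------------------------------------------------------------------

# per-TF printed statistics: tf_id -> (log2fc, padj, K_expressed, k_up, fpkm_case)
_HUMAN_TFS: dict[str, tuple[float, float, int, int, float | None]] = {
    "SPI1": (1.607, 0.016, 6020, 136, 17.91),
    "IRF8": (2.184, 0.004, 754, 24, 10.78),
    "GBX2": (3.360, 0.039, 185, 2, 1.18),
    "IKZF1": (1.230, 0.004, 101, 4, 1.89),
    "TP53": (0.268, 0.967, 3930, 73, None),
    "RELA": (0.074, 0.998, 870, 36, None),
}
_ZF_TFS: dict[str, tuple[float, float, int, int, float | None]] = {
    "spi1b": (1.431, 0.041, 6170, 737, None),
    "irf8": (0.572, 0.224, 720, 78, None),
    "gbx2": (0.017, 0.986, 197, 6, None),
    "ikzf1": (0.962, 0.039, 143, 16, None),
    "tp53": (0.572, 0.010, 4362, 353, None),
    "rela": (-0.694, 0.431, 967, 117, None),
}
_TF_ORTHOLOGS = {
    "SPI1": "spi1b", "IRF8": "irf8", "GBX2": "gbx2",
    "IKZF1": "ikzf1", "TP53": "tp53", "RELA": "rela",
}
_HUMAN_N_UP = 269
_ZF_N_UP = 1820

# Membership classes: (frozenset of human-cased TF ids) -> count per species.
# Chosen so every per-TF sum matches the printed (K, k) pairs and the
# dominant-regulon overlap (18 of IRF8's 24 upregulated targets are also
# SPI1 targets) holds; identical class structure in both species makes the
# class-wise ortholog map exact.
_S = frozenset
_UP_CLASSES: list[tuple[frozenset[str], int, int]] = [
    (_S({"SPI1", "IRF8", "GBX2", "IKZF1", "TP53", "RELA"}), 2, 6),
    (_S({"SPI1", "IRF8", "IKZF1", "TP53", "RELA"}), 2, 10),
    (_S({"SPI1", "IRF8", "TP53", "RELA"}), 14, 44),
    (_S({"SPI1", "TP53", "RELA"}), 18, 57),
    (_S({"SPI1", "TP53"}), 37, 236),
    (_S({"SPI1"}), 63, 384),
    (_S({"IRF8"}), 6, 18),
]
_NONUP_CLASSES: list[tuple[frozenset[str], int, int]] = [
    (_S({"SPI1", "IRF8", "GBX2", "IKZF1", "TP53", "RELA"}), 97, 127),
    (_S({"SPI1", "IRF8", "GBX2", "TP53", "RELA"}), 86, 64),
    (_S({"SPI1", "IRF8", "TP53", "RELA"}), 547, 451),
    (_S({"SPI1", "TP53", "RELA"}), 104, 208),
    (_S({"SPI1", "TP53"}), 3023, 3159),
    (_S({"SPI1"}), 2027, 1424),
]


@dataclass
class Table1Fixture:
    """Paired count-faithful fixtures for the two-species enrichment table."""

    human_de: DETable
    human_db: RegulonDB
    zebrafish_de: DETable
    zebrafish_db: RegulonDB
    ortholog_map: OrthologMap
    human_tf_universe: GeneSetCollection


def _build_species(
    tfs: dict[str, tuple[float, float, int, int, float | None]],
    n_up: int,
    universe: int,
    up_col: int,
    prefix: str,
    lower: bool,
) -> tuple[DETable, RegulonDB, dict[tuple[bool, frozenset[str]], list[str]], str]:
    species = "zebrafish" if lower else "human"
    nonup_class_total = sum(c[up_col] for c in _NONUP_CLASSES)
    if universe < n_up + nonup_class_total + 1:
        raise DomainError(
            f"universe {universe} too small: need at least "
            f"{n_up + nonup_class_total + 1} genes to satisfy the printed counts"
        )

    def name(i: int) -> str:
        s = f"{prefix}{i:05d}"
        return s.lower() if lower else s.upper()

    classes: dict[tuple[bool, frozenset[str]], list[str]] = {}
    idx = 0
    for sig, *counts in _UP_CLASSES:
        block = [name(i) for i in range(idx, idx + counts[up_col - 1])]
        idx += counts[up_col - 1]
        classes[(True, sig)] = block
    none_up = [name(i) for i in range(idx, n_up)]
    idx = n_up
    classes[(True, _S())] = none_up
    for sig, *counts in _NONUP_CLASSES:
        block = [name(i) for i in range(idx, idx + counts[up_col - 1])]
        idx += counts[up_col - 1]
        classes[(False, sig)] = block
    classes[(False, _S())] = [name(i) for i in range(idx, universe)]

    # the TF genes themselves replace slots in the 'none' classes
    for tf, (log2fc, padj, _K, _k, _fpkm) in tfs.items():
        is_up = padj < 0.05 and log2fc > 0
        classes[(is_up, _S())][_tf_slot(tf, tfs)] = tf

    regulons: dict[str, Regulon] = {}
    canonical = {t.upper(): t for t in tfs}
    for tf_upper in ("SPI1", "IRF8", "GBX2", "IKZF1", "TP53", "RELA"):
        tf = canonical[_TF_ORTHOLOGS[tf_upper].upper()] if lower else tf_upper
        members: set[str] = set()
        for (status, sig), block in classes.items():
            if tf_upper in sig:
                members |= set(block)
        regulons[tf] = Regulon(tf_id=tf, targets=frozenset(members), species=species)

    genes: list[DEGene] = []
    for (status, _sig), block in sorted(classes.items(), key=lambda kv: str(kv[0])):
        for g in block:
            if g in tfs:
                log2fc, padj, _K, _k, fpkm = tfs[g]
                means = (
                    {"case": fpkm, "control": fpkm / 2.0 ** log2fc}
                    if fpkm is not None
                    else {}
                )
                genes.append(DEGene(gene_id=g, log2fc=log2fc, padj=padj,
                                    group_means=means, tested=True))
            else:
                genes.append(
                    DEGene(gene_id=g, log2fc=1.0 if status else 0.0,
                           padj=0.01 if status else 0.5, tested=True)
                )
    de = DETable(species=species, genes=genes)
    db = RegulonDB(regulons=regulons, species=species)
    return de, db, classes, species


def _tf_slot(tf: str, tfs: dict) -> int:
    return list(tfs).index(tf)


def table1_fixture(
    universe_human: int = 16_997,
    universe_zebrafish: int = 20_475,
) -> Table1Fixture:
    """Deterministic two-species fixture honouring the printed (K, k) counts.

    Default universe sizes are the ones the anchor-row calibration
    recovers; both are configurable.  The returned ortholog map sends each
    human gene class onto the same-signature zebrafish class, so
    transferring the human regulon database reproduces the zebrafish
    regulons exactly, and the named TFs map to their published homologs.
    """
    human_de, human_db, h_classes, _ = _build_species(
        _HUMAN_TFS, _HUMAN_N_UP, universe_human, 1, "HG", lower=False
    )
    zf_de, zf_db, z_classes, _ = _build_species(
        _ZF_TFS, _ZF_N_UP, universe_zebrafish, 2, "zg", lower=True
    )

    pairs: set[tuple[str, str]] = set()
    for key, z_block in z_classes.items():
        h_block = [g for g in h_classes[key] if g not in _HUMAN_TFS]
        z_clean = [g for g in z_block if g not in _ZF_TFS]
        for i, z in enumerate(z_clean):
            pairs.add((h_block[i % len(h_block)], z))
    for h_tf, z_tf in _TF_ORTHOLOGS.items():
        pairs.add((h_tf, z_tf))

    # TF universe: the six factors plus 20 annotated-but-uncatalogued genes,
    # so that |upregulated ∩ universe| = 24 of which 4 carry a regulon
    up_none = [g for g in h_classes[(True, _S())] if g not in _HUMAN_TFS]
    universe_members = set(_HUMAN_TFS) | set(up_none[:20])
    tf_universe = GeneSetCollection(
        sets={
            "GO:0003700": ("DNA-binding transcription factor activity",
                           frozenset(universe_members))
        },
        kind="TF-universe",
    )

    return Table1Fixture(
        human_de=human_de,
        human_db=human_db,
        zebrafish_de=zf_de,
        zebrafish_db=zf_db,
        ortholog_map=OrthologMap(
            from_species="human", to_species="zebrafish", pairs=frozenset(pairs)
        ),
        human_tf_universe=tf_universe,
    )
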