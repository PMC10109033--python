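"""Synthetic cohort generator with ground truth.

Generates a protein intensity matrix (log-normal with batch shifts and
abundance-dependent left-censored dropout), a targeted RNA count matrix
(negative binomial with library-size variation), sample metadata, gene
annotation and a :class:`SyntheticTruth` record of everything planted.

The two layers share a per-(gene, sample) latent deviate: the RNA layer sees
the latent directly while the protein layer sees
``rho * latent + sqrt(1 - rho^2) * noise``, so ``rho`` directly tunes the
per-gene protein-mRNA correlation.  Marker genes additionally receive a
per-sample cell-fraction deviate on BOTH layers, which drives their realized
cross-layer correlation above that of non-marker genes.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import log_stage
from .errors import ConfigError, ValidationError
from .matrix_io import (
    CohortMeta,
    ExpressionMatrix,
    GeneAnnotation,
    read_annotation,
    read_matrix,
    read_meta,
    write_annotation,
    write_matrix,
    write_meta,
)

PLANT_KINDS = (
    "concordant_down",
    "protein_only_down",
    "mrna_only_down",
    "b_cell_deficient",
    "t_cell_deficient",
    "global_dropout_outlier",
)

_SINGLE_GENE_KINDS = {"concordant_down", "protein_only_down", "mrna_only_down"}
_CELLDEF_KINDS = {"b_cell_deficient", "t_cell_deficient"}


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    Counts and noise scales are chosen to emulate a proteome-wide intensity
    matrix plus a targeted RNA panel over a patients+controls cohort.
    """

    n_patients: int = 63
    n_controls: int = 6
    n_genes_protein: int = 2000
    n_genes_targeted: int = 300
    n_batches: int = 3
    batch_shift_sd: float = 0.3
    base_mean_log2: float = 20.0
    gene_sd_log2: float = 2.5
    censor_midpoint: float = 16.0
    censor_slope: float = 1.0
    rna_dispersion: float = 0.1
    libsize_sd_log: float = 0.2
    seed: int = 0
    # latent-structure knobs (defaults are sensible for all tests)
    within_sd_log2: float = 1.0
    rho_default: float = 0.3
    rho_marker: float = 0.85
    n_markers_b: int = 5
    n_markers_t: int = 5
    cellfrac_sd_log2: float = 1.5
    n_rbc: int = 0
    n_plasma: int = 0
    nontarget_shift_log2: float = 4.0
    rna_base_mean_log2: float = 6.0
    rna_gene_sd_log2: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_patients",
            "n_controls",
            "n_genes_protein",
            "n_genes_targeted",
            "n_batches",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_controls < 2:
            raise ConfigError("n_controls must be >= 2")
        if self.censor_slope <= 0:
            raise ConfigError("censor_slope must be > 0")
        if self.rna_dispersion <= 0:
            raise ConfigError("rna_dispersion must be > 0")
        if self.n_genes_targeted > self.n_genes_protein:
            raise ConfigError("n_genes_targeted cannot exceed n_genes_protein")
        if self.n_markers_b + self.n_markers_t > self.n_genes_targeted:
            raise ConfigError("marker genes must fit inside the targeted panel")
        if self.n_rbc + self.n_plasma > self.n_genes_protein - self.n_genes_targeted:
            raise ConfigError("rbc/plasma genes must fit outside the targeted panel")
        if not -1.0 <= self.rho_default <= 1.0 or not -1.0 <= self.rho_marker <= 1.0:
            raise ConfigError("correlation parameters must lie in [-1, 1]")


@dataclass(frozen=True)
class PlantSpec:
    """One planted effect: a disease case, a cell deficiency, or a dropout outlier."""

    kind: str
    sample_id: str
    effect_log2: float
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ValidationError(f"unknown plant kind {self.kind!r}")
        if self.effect_log2 <= 0:
            raise ValidationError("effect_log2 must be > 0")
        if self.kind in _SINGLE_GENE_KINDS and not self.gene:
            raise ValidationError(f"{self.kind} plant requires exactly one target gene")
        if self.kind not in _SINGLE_GENE_KINDS and self.gene is not None:
            raise ValidationError(f"{self.kind} plant must not name a gene")

    def layers(self) -> tuple[str, ...]:
        if self.kind == "concordant_down":
            return ("protein", "rna")
        if self.kind == "protein_only_down":
            return ("protein",)
        if self.kind == "mrna_only_down":
            return ("rna",)
        if self.kind in _CELLDEF_KINDS:
            return ("protein", "rna")
        return ()


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, sufficient to regenerate it."""

    config: SimConfig
    planted: list[PlantSpec]
    true_gene_corr: dict[str, float]
    censor_midpoint: float
    censor_slope: float
    libsize: dict[str, float]
    batch: dict[str, str]
    marker_genes: dict[str, list[str]]

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "planted": [dataclasses.asdict(p) for p in self.planted],
            "true_gene_corr": self.true_gene_corr,
            "censor_midpoint": self.censor_midpoint,
            "censor_slope": self.censor_slope,
            "libsize": self.libsize,
            "batch": self.batch,
            "marker_genes": self.marker_genes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            config=SimConfig(**d["config"]),
            planted=[PlantSpec(**p) for p in d["planted"]],
            true_gene_corr=d["true_gene_corr"],
            censor_midpoint=d["censor_midpoint"],
            censor_slope=d["censor_slope"],
            libsize=d["libsize"],
            batch=d["batch"],
            marker_genes=d["marker_genes"],
        )


def _sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    controls = [f"C{i + 1:02d}" for i in range(config.n_controls)]
    return patients, controls


def _gene_ids(config: SimConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(config.n_genes_protein)]


def simulate_cohort(
    config: SimConfig, plants: list[PlantSpec] | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortMeta, GeneAnnotation, SyntheticTruth]:
    """Simulate a two-layer cohort and return matrices, metadata and truth.

    Planted effects subtract ``effect_log2`` from the designated
    layer(s)/genes/samples on the log2 scale *before* protein censoring, so a
    knocked-down protein can fall below the detection limit and go missing.
    """
    plants = list(plants or [])
    rng = np.random.default_rng(config.seed)

    patients, controls = _sample_ids(config)
    samples = patients + controls
    genes = _gene_ids(config)
    n_s, n_g = len(samples), len(genes)

    # -- id spaces -------------------------------------------------------
    targeted = genes[: config.n_genes_targeted]
    markers_b = targeted[: config.n_markers_b]
    markers_t = targeted[config.n_markers_b : config.n_markers_b + config.n_markers_t]
    nontarget_pool = genes[config.n_genes_targeted :]
    rbc_genes = nontarget_pool[: config.n_rbc]
    plasma_genes = nontarget_pool[config.n_rbc : config.n_rbc + config.n_plasma]
    targeted_set = set(targeted)
    nontarget_set = set(rbc_genes) | set(plasma_genes)

    _validate_plants(plants, samples, genes, targeted_set)

    # -- latent structure (all randomness drawn before plants apply) -----
    gene_mu = config.base_mean_log2 + config.gene_sd_log2 * rng.standard_normal(n_g)
    nontarget_idx = np.array([g in nontarget_set for g in genes])
    gene_mu[nontarget_idx] += config.nontarget_shift_log2

    rna_mu = config.rna_base_mean_log2 + config.rna_gene_sd_log2 * rng.standard_normal(n_g)

    batch_names = [f"B{i + 1}" for i in range(config.n_batches)] + ["Ctrl"]
    batch_shift = dict(
        zip(batch_names, config.batch_shift_sd * rng.standard_normal(len(batch_names)))
    )
    sample_batch = {
        s: batch_names[i % config.n_batches] for i, s in enumerate(patients)
    }
    sample_batch.update({s: "Ctrl" for s in controls})

    latent = rng.standard_normal((n_g, n_s))
    protein_noise = rng.standard_normal((n_g, n_s))
    cellfrac_b = config.cellfrac_sd_log2 * rng.standard_normal(n_s)
    cellfrac_t = config.cellfrac_sd_log2 * rng.standard_normal(n_s)
    libsize = np.exp(config.libsize_sd_log * rng.standard_normal(n_s))
    censor_u = rng.uniform(size=(n_g, n_s))

    rho = np.full(n_g, config.rho_default)
    marker_idx_b = np.array([g in set(markers_b) for g in genes])
    marker_idx_t = np.array([g in set(markers_t) for g in genes])
    rho[marker_idx_b | marker_idx_t] = config.rho_marker

    sd = config.within_sd_log2
    dev_rna = latent
    dev_prot = rho[:, None] * latent + np.sqrt(1.0 - rho[:, None] ** 2) * protein_noise

    shift = np.array([batch_shift[sample_batch[s]] for s in samples])
    prot_log2 = gene_mu[:, None] + shift[None, :] + sd * dev_prot
    rna_log2 = rna_mu[:, None] + sd * dev_rna

    prot_log2[marker_idx_b] += cellfrac_b[None, :]
    rna_log2[marker_idx_b] += cellfrac_b[None, :]
    prot_log2[marker_idx_t] += cellfrac_t[None, :]
    rna_log2[marker_idx_t] += cellfrac_t[None, :]

    # -- planted effects (deterministic) ---------------------------------
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    midpoint_shift = np.zeros(n_s)
    for p in plants:
        j = sample_pos[p.sample_id]
        if p.kind == "global_dropout_outlier":
            midpoint_shift[j] += p.effect_log2
            continue
        if p.kind in _SINGLE_GENE_KINDS:
            rows = [gene_pos[p.gene]]
        else:
            panel = markers_b if p.kind == "b_cell_deficient" else markers_t
            rows = [gene_pos[g] for g in panel]
        for i in rows:
            if "protein" in p.layers():
                prot_log2[i, j] -= p.effect_log2
            if "rna" in p.layers():
                rna_log2[i, j] -= p.effect_log2

    # -- protein censoring (left-censored MNAR dropout) -------------------
    p_missing = expit(
        (config.censor_midpoint + midpoint_shift[None, :] - prot_log2)
        * config.censor_slope
    )
    missing = censor_u < p_missing
    prot_linear = np.power(2.0, prot_log2)
    prot_linear[missing] = np.nan

    protein = ExpressionMatrix(
        pd.DataFrame(prot_linear, index=genes, columns=samples),
        pd.DataFrame(missing, index=genes, columns=samples),
        layer="protein",
        scale="linear",
    )

    # -- targeted RNA counts (gamma-Poisson == NB) ------------------------
    t_idx = np.array([g in targeted_set for g in genes])
    rna_mean = libsize[None, :] * np.power(2.0, rna_log2[t_idx])
    shape = 1.0 / config.rna_dispersion
    lam = rng.gamma(shape, rna_mean * config.rna_dispersion)
    counts = rng.poisson(lam).astype(float)
    rna = ExpressionMatrix(
        pd.DataFrame(counts, index=targeted, columns=samples),
        pd.DataFrame(False, index=targeted, columns=samples),
        layer="rna",
        scale="linear",
    )

    # -- metadata / annotation / truth ------------------------------------
    meta = CohortMeta(
        pd.DataFrame(
            {
                "role": ["patient"] * len(patients) + ["control"] * len(controls),
                "batch": [sample_batch[s] for s in samples],
                "excluded": False,
                "exclusion_reason": "",
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "targeted_panel": [g in targeted_set for g in genes],
                "nontarget_category": [
                    "rbc" if g in set(rbc_genes) else "plasma" if g in set(plasma_genes) else "none"
                    for g in genes
                ],
                "cell_marker": [
                    "b_cell" if marker_idx_b[i] else "t_cell" if marker_idx_t[i] else "none"
                    for i, g in enumerate(genes)
                ],
                "coding": True,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    truth = SyntheticTruth(
        config=config,
        planted=plants,
        true_gene_corr={g: float(rho[i]) for i, g in enumerate(genes)},
        censor_midpoint=config.censor_midpoint,
        censor_slope=config.censor_slope,
        libsize={s: float(libsize[j]) for j, s in enumerate(samples)},
        batch=dict(sample_batch),
        marker_genes={"b_cell": list(markers_b), "t_cell": list(markers_t)},
    )
    log_stage(
        "simulate",
        f"{n_g} protein genes x {n_s} samples, {len(targeted)} targeted, "
        f"{int(missing.sum())} censored cells, {len(plants)} plants",
    )
    return protein, rna, meta, annot, truth


def _validate_plants(
    plants: list[PlantSpec],
    samples: list[str],
    genes: list[str],
    targeted: set[str],
) -> None:
    sample_set, gene_set = set(samples), set(genes)
    seen: set[tuple] = set()
    for p in plants:
        if p.sample_id not in sample_set:
            raise ValidationError(f"plant references unknown sample {p.sample_id!r}")
        if p.gene is not None:
            if p.gene not in gene_set:
                raise ValidationError(f"plant references unknown gene {p.gene!r}")
            if "rna" in p.layers() and p.gene not in targeted:
                raise ValidationError(
                    f"plant {p.kind} on {p.gene!r} needs the gene on the RNA panel"
                )
        for layer in p.layers() or ("sample",):
            key = (p.gene, p.sample_id, layer, p.kind in _CELLDEF_KINDS)
            if key in seen:
                raise ValidationError(
                    f"duplicate plant on (gene={p.gene}, sample={p.sample_id}, layer={layer})"
                )
            seen.add(key)


FIXTURE_FILES = {
    "protein": "protein.tsv",
    "rna": "rna.tsv",
    "meta": "meta.tsv",
    "annotation": "annotation.tsv",
    "truth": "truth.json",
}


def write_fixture(
    dir_path: str | os.PathLike,
    protein: ExpressionMatrix,
    rna: ExpressionMatrix,
    meta: CohortMeta,
    annot: GeneAnnotation,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Serialize a simulated cohort as plain-text files; round-trips losslessly."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FIXTURE_FILES.items()}
    write_matrix(protein, paths["protein"])
    write_matrix(rna, paths["rna"])
    write_meta(meta, paths["meta"])
    write_annotation(annot, paths["annotation"])
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths


def read_fixture(
    dir_path: str | os.PathLike,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortMeta, GeneAnnotation, SyntheticTruth | None]:
    """Load a cohort written by :func:`write_fixture` (truth optional)."""
    d = Path(dir_path)
    protein = read_matrix(d / FIXTURE_FILES["protein"], layer="protein")
    rna = read_matrix(d / FIXTURE_FILES["rna"], layer="rna")
    meta = read_meta(d / FIXTURE_FILES["meta"])
    annot = read_annotation(d / FIXTURE_FILES["annotation"])
    truth_path = d / FIXTURE_FILES["truth"]
    truth = (
        SyntheticTruth.from_json(truth_path.read_text(encoding="utf-8"))
        if truth_path.exists()
        else None
    )
    return protein, rna, meta, annot, truth
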