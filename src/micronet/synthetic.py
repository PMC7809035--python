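"""Synthetic cohort generator with known ground truth.

Emulates the structure of a brain-aging cohort study at desk scale: a
module-structured bulk expression matrix, sorted-cell reference profiles
obeying the fourfold signature rule, longitudinal cognition with
person-specific slopes, segmented-cell images whose ramification depends
on marker positivity, a four-cluster single-nucleus count matrix with one
module-5-high cluster tracking tau, and a GWAS probe table with planted
susceptibility genes.

The causal ground truth follows two chains:
``sex -> m114 -> amyloid -> cognitive decline`` and
``m5 -> tau -> cognitive decline``, with standardized path coefficients.
Sex is coded 0 = male, 1 = female and enters the structural equations as a
+/-1 contrast; tests built on the generator compare coefficient magnitudes
and the generator's documented directions.

All randomness flows from one root seed through named child streams (one
per output), so adding an output never perturbs existing ones.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk, line as _draw_line

from .preprocess import ExpressionMatrix, ModuleAssignment
from .snrna import SnCountMatrix

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "LongitudinalCognition",
    "ImageSet",
    "generate_cohort",
    "generate_reference_profiles",
    "generate_longitudinal",
    "generate_cell_images",
    "generate_sn_counts",
    "generate_gwas_summary",
    "write_tiffs",
]

IMMUNE_MODULES = ("m5", "m113", "m114", "m115", "m116")
CELLTYPE_MODULES = {"m21": "neuron", "m107": "astrocyte", "m110": "oligodendrocyte", "m112": "endothelial"}
BACKGROUND_MODULES = ("m1", "m2", "m3")

#: default standardized path coefficients for the two causal chains;
#: module-level paths sit at 0.25-0.35, while the tau -> decline coupling is
#: stronger (0.5), matching its dominant role in cognitive aging cohorts
DEFAULT_COEFFS = {
    "sex->m114": 0.30,
    "m114->amyloid": 0.30,
    "m113->amyloid": 0.25,
    "m5->tau": 0.35,
    "tau->cogdec": 0.50,
    "amyloid->cogdec": 0.25,
    "age->m116": 0.30,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth configuration for every synthetic output."""

    module_defs: dict  # module -> {gene: loading}
    causal_coeffs: dict
    noise_sds: dict  # keys: gene, module, amyloid, tau, cogdec
    n_subjects: int
    n_genes: int
    seed: int
    signature_spec: dict  # cell type -> list of genes (>= fourfold enriched)

    def validate(self) -> None:
        seen = set()
        for module, genes in self.module_defs.items():
            if seen & set(genes):
                raise ValueError(f"module {module} overlaps another module")
            seen |= set(genes)
        sig_seen = set()
        for ct, genes in self.signature_spec.items():
            if sig_seen & set(genes):
                raise ValueError(f"signature genes of {ct} overlap another cell type")
            sig_seen |= set(genes)
        if any(sd < 0 for sd in self.noise_sds.values()):
            raise ValueError("noise standard deviations must be nonnegative")
        for key in DEFAULT_COEFFS:
            if key not in self.causal_coeffs:
                raise ValueError(f"missing causal coefficient {key!r}")

    def validate_cohort(self) -> None:
        self.validate()
        if self.n_subjects < 30:
            raise ValueError("cohort generation requires n_subjects >= 30")
        for module, genes in self.module_defs.items():
            if len(genes) < 20:
                raise ValueError(f"module {module} has fewer than 20 genes")
        if any(sd <= 0 for sd in self.noise_sds.values()):
            raise ValueError("noise variances must be strictly positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child stream: independent of every other stream name.

        Counter-based Philox keyed by (seed, stream hash) gives clean
        independence both across stream names and across nearby seeds.
        """
        return np.random.Generator(
            np.random.Philox(
                np.random.SeedSequence([self.seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
            )
        )

    @property
    def gene_ids(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def assignment(self) -> ModuleAssignment:
        mapping = {}
        for module, genes in self.module_defs.items():
            for g in genes:
                mapping[g] = module
        return ModuleAssignment(pd.Series(mapping, name="module_id"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def default_truth(
    seed: int = 0,
    n_subjects: int = 400,
    genes_per_module: int = 25,
    n_unassigned: int = 100,
    coeffs: dict | None = None,
    gene_noise_sd: float = 0.5,
) -> SyntheticTruth:
    """Study-condition defaults: 12 modules of 25 genes, two causal chains.

    Trait residual SDs are set so every latent (module activity, amyloid,
    tau, decline) has unit variance, making the path coefficients
    standardized.
    """
    coeffs = dict(DEFAULT_COEFFS if coeffs is None else coeffs)
    modules = [*IMMUNE_MODULES, *CELLTYPE_MODULES, *BACKGROUND_MODULES]
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(b"truth")]))
    )
    module_defs, idx = {}, 0
    for module in modules:
        genes = [f"G{i:04d}" for i in range(idx, idx + genes_per_module)]
        idx += genes_per_module
        module_defs[module] = {g: float(rng.uniform(0.5, 1.0)) for g in genes}
    n_genes = idx + n_unassigned
    signature_spec = {
        "microglia": [g for m in IMMUNE_MODULES for g in module_defs[m]],
        "astrocyte": list(module_defs["m107"]),
        "neuron": list(module_defs["m21"]),
    }

    def resid(*cs):
        return math.sqrt(max(1.0 - sum(c * c for c in cs), 0.05))

    noise_sds = {
        "gene": gene_noise_sd,
        "module": 1.0,  # modules without parents; parented modules use resid()
        "amyloid": resid(coeffs["m114->amyloid"], coeffs["m113->amyloid"]),
        "tau": resid(coeffs["m5->tau"]),
        "cogdec": resid(coeffs["tau->cogdec"], coeffs["amyloid->cogdec"]),
    }
    return SyntheticTruth(
        module_defs=module_defs,
        causal_coeffs=coeffs,
        noise_sds=noise_sds,
        n_subjects=n_subjects,
        n_genes=n_genes,
        seed=seed,
        signature_spec=signature_spec,
    )


# ---------------------------------------------------------------------------
# subject-level latents (shared by cohort, longitudinal, imaging, snRNA-seq)
# ---------------------------------------------------------------------------

def _subject_latents(truth: SyntheticTruth) -> pd.DataFrame:
    n = truth.n_subjects
    c = truth.causal_coeffs
    rng = truth.rng("subjects")
    sex = rng.integers(0, 2, n).astype(float)
    sex_c = 2.0 * sex - 1.0  # +/-1 contrast, unit variance
    study = rng.integers(0, 2, n).astype(float)
    age_z = rng.standard_normal(n)
    rin_z = rng.standard_normal(n)
    pmi_z = rng.standard_normal(n)
    edu_z = rng.standard_normal(n)

    def child(c_val, parent):
        eps = rng.standard_normal(n)
        return c_val * parent + math.sqrt(max(1.0 - c_val**2, 0.05)) * eps

    activities = {}
    for module in sorted(truth.module_defs):
        if module == "m114":
            activities[module] = child(c["sex->m114"], sex_c)
        elif module == "m116":
            activities[module] = child(c["age->m116"], age_z)
        else:
            activities[module] = truth.noise_sds.get("module", 1.0) * rng.standard_normal(n)

    amyloid_lat = (
        c["m114->amyloid"] * activities.get("m114", 0)
        + c["m113->amyloid"] * activities.get("m113", 0)
        + truth.noise_sds["amyloid"] * rng.standard_normal(n)
    )
    tau_lat = c["m5->tau"] * activities.get("m5", 0) + truth.noise_sds["tau"] * rng.standard_normal(n)
    cogdec_lat = (
        c["tau->cogdec"] * tau_lat
        + c["amyloid->cogdec"] * amyloid_lat
        + truth.noise_sds["cogdec"] * rng.standard_normal(n)
    )
    amyloid_sqrt = np.clip(2.0 + 0.8 * amyloid_lat, 0.0, None)
    tau_sqrt = np.clip(1.5 + 0.6 * tau_lat, 0.0, None)
    frame = pd.DataFrame(
        {
            "sex": sex,
            "sex_c": sex_c,
            "study": study,
            "age_death": 85.0 + 6.0 * age_z,
            "age_z": age_z,
            "rin": np.clip(7.0 + rin_z, 4.0, 10.0),
            "rin_z": rin_z,
            "pmi": np.clip(7.0 + 3.0 * pmi_z, 0.5, None),
            "pmi_z": pmi_z,
            "education": np.clip(np.round(16.0 + 3.0 * edu_z), 8, 25),
            "amyloid_lat": amyloid_lat,
            "tau_lat": tau_lat,
            "cogdec_lat": cogdec_lat,
            # more pathology-driven decline => more negative slope
            "decline_slope": -0.05 - 0.10 * cogdec_lat,
            "amyloid_sqrt": amyloid_sqrt,
            "amyloid": amyloid_sqrt**2,
            "tau_sqrt": tau_sqrt,
            "tau": tau_sqrt**2,
            "np": np.clip(1.5 + 0.9 * amyloid_lat + 0.8 * rng.standard_normal(n), 0.0, None),
            "nft": np.clip(1.5 + 0.9 * tau_lat + 0.8 * rng.standard_normal(n), 0.0, None),
            "dp": np.clip(1.5 + 0.8 * amyloid_lat + 0.9 * rng.standard_normal(n), 0.0, None),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
    )
    for module, act in activities.items():
        frame[f"act_{module}"] = act
    # ordinal stages from pathology quantiles
    frame["braak"] = pd.qcut(frame["tau_sqrt"].rank(method="first"), 7, labels=False)
    frame["cerad"] = pd.qcut(frame["np"].rank(method="first"), 4, labels=False)
    frame["niareagan"] = 1 + pd.qcut(frame["amyloid_sqrt"].rank(method="first"), 4, labels=False)
    return frame


_PHENOTYPE_COLUMNS = [
    "amyloid_sqrt",
    "tau_sqrt",
    "amyloid",
    "tau",
    "np",
    "nft",
    "dp",
    "decline_slope",
    "age_death",
    "sex",
    "study",
    "rin",
    "pmi",
    "education",
    "braak",
    "cerad",
    "niareagan",
]


def generate_cohort(truth: SyntheticTruth):
    """Expression matrix (FPKM), module assignment, and phenotype table.

    Gene expression is built on the log2 scale (baseline + loading x module
    activity + technical effects + noise) and exponentiated, so FPKM > 0
    everywhere. Technical structure includes RIN/PMI gradients and a
    study-batch shift so the preprocessing stages have real work to do.
    """
    truth.validate_cohort()
    latents = _subject_latents(truth)
    rng = truth.rng("expression")
    genes = truth.gene_ids
    assignment = truth.assignment()
    in_module = np.array([g in assignment.mapping.index for g in genes])
    baseline = np.where(
        in_module, rng.normal(3.0, 1.0, truth.n_genes), rng.normal(1.5, 1.5, truth.n_genes)
    )
    rin_coef = rng.normal(0.0, 0.08, truth.n_genes)
    pmi_coef = rng.normal(0.0, 0.05, truth.n_genes)
    batch_coef = rng.normal(0.0, 0.2, truth.n_genes)
    loading = np.zeros(truth.n_genes)
    activity = np.zeros((truth.n_genes, truth.n_subjects))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for module, members in truth.module_defs.items():
        act = latents[f"act_{module}"].to_numpy()
        for g, lo in members.items():
            loading[gene_pos[g]] = lo
            activity[gene_pos[g]] = act
    log2x = (
        baseline[:, None]
        + loading[:, None] * activity
        + rin_coef[:, None] * latents["rin_z"].to_numpy()[None, :]
        + pmi_coef[:, None] * latents["pmi_z"].to_numpy()[None, :]
        + batch_coef[:, None] * latents["study"].to_numpy()[None, :]
        + truth.noise_sds["gene"] * rng.standard_normal((truth.n_genes, truth.n_subjects))
    )
    fpkm = pd.DataFrame(np.exp2(log2x), index=pd.Index(genes, name="gene_id"), columns=latents.index)
    expr = ExpressionMatrix(fpkm, unit="fpkm")
    phen = latents[_PHENOTYPE_COLUMNS].copy()
    return expr, assignment, phen


def generate_reference_profiles(truth: SyntheticTruth, n_replicates: int = 8) -> dict:
    """Sorted-cell and bulk FPKM reference profiles honoring the fourfold rule.

    Every designated signature gene of a cell type has mean FPKM in that
    type at least 4x its bulk mean and above 1; every other gene stays
    within a factor ~1 of bulk, so the rule recovers the planted sets
    exactly.
    """
    if not truth.signature_spec:
        raise ValueError("signature_spec is empty")
    rng = truth.rng("profiles")
    genes = pd.Index(truth.gene_ids, name="gene_id")
    bulk_mean = np.maximum(np.exp2(rng.normal(2.5, 1.0, truth.n_genes)), 0.3)

    def matrix(mean):
        reps = mean[:, None] * np.exp2(rng.normal(0.0, 0.05, (truth.n_genes, n_replicates)))
        cols = [f"rep{j}" for j in range(n_replicates)]
        return ExpressionMatrix(pd.DataFrame(reps, index=genes, columns=cols), unit="fpkm")

    profiles = {"bulk": matrix(bulk_mean)}
    for cell_type, members in truth.signature_spec.items():
        if not members:
            raise ValueError(f"empty signature for cell type {cell_type!r}")
        member_set = set(members)
        factor = rng.uniform(0.85, 1.1, truth.n_genes)
        factor[[g in member_set for g in genes]] = 6.0
        profiles[cell_type] = matrix(bulk_mean * factor)
    return profiles


# ---------------------------------------------------------------------------
# longitudinal cognition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalCognition:
    """Annual cognition scores plus the generator's true per-subject slopes."""

    observations: pd.DataFrame  # subject_id, year, cognition, age, sex, education
    true_slopes: pd.Series


def generate_longitudinal(
    truth: SyntheticTruth, visits: int = 8, resid_sd: float = 0.25
) -> LongitudinalCognition:
    """Per-subject linear cognitive trajectories with annual visits.

    Observed score = subject intercept + slope x year + age/sex/education
    level effects + N(0, resid_sd^2). The slope is the subject's
    ``decline_slope`` latent, shared with the cohort phenotype table.
    """
    if visits < 3:
        raise ValueError("need at least 3 visits for identifiable slopes")
    if resid_sd < 0:
        raise ValueError("residual SD must be nonnegative")
    latents = _subject_latents(truth)
    rng = truth.rng("longitudinal")
    n = truth.n_subjects
    intercept = 0.25 * rng.standard_normal(n)
    age_c = latents["age_death"].to_numpy() - 85.0
    edu_c = latents["education"].to_numpy() - 16.0
    level = intercept - 0.02 * age_c + 0.10 * latents["sex"].to_numpy() + 0.03 * edu_c
    years = np.arange(visits, dtype=float)
    rows = []
    noise = rng.normal(0.0, resid_sd, (n, visits)) if resid_sd > 0 else np.zeros((n, visits))
    slopes = latents["decline_slope"].to_numpy()
    for i, sid in enumerate(latents.index):
        for j, year in enumerate(years):
            rows.append(
                {
                    "subject_id": sid,
                    "year": year,
                    "cognition": level[i] + slopes[i] * year + noise[i, j],
                    "age": latents["age_death"].iloc[i],
                    "sex": latents["sex"].iloc[i],
                    "education": latents["education"].iloc[i],
                }
            )
    return LongitudinalCognition(
        observations=pd.DataFrame(rows),
        true_slopes=latents["decline_slope"].copy(),
    )


# ---------------------------------------------------------------------------
# segmented-cell images
# ---------------------------------------------------------------------------

@dataclass
class ImageSet:
    """Per-subject masks and marker channels, with planted positivity truth."""

    subject_ids: list
    masks: list  # binary uint16 images
    channels: dict  # marker -> list of uint16 images
    positive_truth: list  # boolean images marking planted marker+ cells
    stages: pd.Series  # per-subject Braak-like stage
    cells_per_subject: int
    effect: float


_GRID = 40  # grid pitch in px; max blob reach 16 px keeps blobs disjoint


def _draw_cell(mask, center, ram, rng):
    h, w = mask.shape
    r = int(rng.integers(2, 5))
    rr, cc = _draw_disk(center, r, shape=mask.shape)
    mask[rr, cc] = True
    angles = rng.uniform(0.0, 2.0 * np.pi, 5)
    lengths = np.clip(rng.normal(4.0 + 9.0 * ram, 1.5, 5), 1.0, 14.0)
    for angle, length in zip(angles, lengths):
        end_r = int(round(center[0] + length * np.sin(angle)))
        end_c = int(round(center[1] + length * np.cos(angle)))
        end_r = min(max(end_r, 0), h - 1)
        end_c = min(max(end_c, 0), w - 1)
        rr, cc = _draw_line(center[0], center[1], end_r, end_c)
        mask[rr, cc] = True


def generate_cell_images(
    truth: SyntheticTruth,
    cells_per_subject: int,
    n_subjects: int = 6,
    effect: float = -0.3,
    markers: tuple = ("TMEM119", "VASP"),
    image_shape: tuple | None = None,
) -> ImageSet:
    """Binary masks plus pan-marker and subset-marker channels.

    Marker-positive cells are drawn from a less ramified (disk-like, lower
    compactness) shape family than marker-negative cells; ``effect`` shifts
    the mean ramification of positives (negative = rounder). The positive
    fraction rises with the subject's tau stage. The pan marker is bright
    on every cell; the subset marker only on planted positives.
    """
    if cells_per_subject < 10:
        raise ValueError("need at least 10 cells per subject")
    latents = _subject_latents(truth)
    if n_subjects > len(latents):
        raise ValueError("more imaging subjects than cohort subjects")
    rng = truth.rng("images")
    ncols = math.ceil(math.sqrt(cells_per_subject))
    nrows = math.ceil(cells_per_subject / ncols)
    shape = (nrows * _GRID, ncols * _GRID) if image_shape is None else tuple(image_shape)
    capacity = (shape[0] // _GRID) * (shape[1] // _GRID)
    if capacity < cells_per_subject:
        raise ValueError(
            f"cannot place {cells_per_subject} non-overlapping cells in a {shape} image "
            f"(packing limit {capacity})"
        )
    pan, sub = markers
    subjects = latents.index[:n_subjects].tolist()
    stages = latents.loc[subjects, "braak"].astype(float)
    masks, truth_imgs = [], []
    channels = {pan: [], sub: []}
    for sid in subjects:
        subject_re = rng.normal(0.0, 0.12)
        p_pos = float(np.clip(0.15 + 0.06 * stages[sid], 0.05, 0.9))
        mask = np.zeros(shape, dtype=bool)
        pos_img = np.zeros(shape, dtype=bool)
        slots = [(i, j) for i in range(shape[0] // _GRID) for j in range(shape[1] // _GRID)]
        for k in range(cells_per_subject):
            gi, gj = slots[k]
            center = (
                gi * _GRID + _GRID // 2 + int(rng.integers(-2, 3)),
                gj * _GRID + _GRID // 2 + int(rng.integers(-2, 3)),
            )
            is_pos = bool(rng.random() < p_pos)
            ram = max(0.05, 1.0 + (effect if is_pos else 0.0) + subject_re + rng.normal(0.0, 0.35))
            cell_mask = np.zeros(shape, dtype=bool)
            _draw_cell(cell_mask, center, ram, rng)
            mask |= cell_mask
            if is_pos:
                pos_img |= cell_mask
        base_pan = rng.normal(500.0, 60.0, shape)
        base_sub = rng.normal(500.0, 60.0, shape)
        pan_img = np.where(mask, 3000.0 + rng.normal(0.0, 150.0, shape), base_pan)
        sub_img = np.where(
            pos_img,
            3000.0 + rng.normal(0.0, 150.0, shape),
            np.where(mask, 800.0 + rng.normal(0.0, 80.0, shape), base_sub),
        )
        masks.append(mask.astype(np.uint16))
        truth_imgs.append(pos_img)
        channels[pan].append(np.clip(pan_img, 0, 65535).astype(np.uint16))
        channels[sub].append(np.clip(sub_img, 0, 65535).astype(np.uint16))
    return ImageSet(
        subject_ids=subjects,
        masks=masks,
        channels=channels,
        positive_truth=truth_imgs,
        stages=stages,
        cells_per_subject=cells_per_subject,
        effect=effect,
    )


def write_tiffs(images: ImageSet, outdir) -> None:
    """16-bit TIFFs: one mask plus one image per channel per subject."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(images.subject_ids):
        tifffile.imwrite(outdir / f"{sid}_mask.tif", images.masks[i])
        for marker, imgs in images.channels.items():
            tifffile.imwrite(outdir / f"{sid}_{marker}.tif", imgs[i])


# ---------------------------------------------------------------------------
# single-nucleus counts
# ---------------------------------------------------------------------------

def generate_sn_counts(
    truth: SyntheticTruth,
    cells: int,
    n_clusters: int = 4,
    m5_factor: float = 2.0,
    tau_effect: float = 0.8,
) -> SnCountMatrix:
    """Four-cluster microglial nuclei with a module-5-high first cluster.

    Cluster-1 cells have the m5 genes' mean expression multiplied by
    ``m5_factor``; each subject's probability of contributing cluster-1
    cells increases with that subject's (standardized) tau burden through a
    softmax weight exp(tau_effect * tau_z). Counts follow a
    Poisson-lognormal scheme: per-cell depth and per-cell-gene lognormal
    jitter around cluster-specific expected profiles.
    """
    if n_clusters < 4:
        raise ValueError("at least 4 microglial clusters are required")
    if cells < 4 * truth.n_subjects:
        raise ValueError("need at least 4 cells per subject on average")
    latents = _subject_latents(truth)
    rng = truth.rng("snrna")
    tau = latents["tau_sqrt"]
    tau_z = ((tau - tau.mean()) / tau.std(ddof=1)).to_numpy()
    n_subj = truth.n_subjects
    subject_idx = np.concatenate(
        [np.arange(n_subj), rng.integers(0, n_subj, cells - n_subj)]
    )
    rng.shuffle(subject_idx)
    w1 = np.exp(tau_effect * tau_z[subject_idx])
    p1 = w1 / (w1 + (n_clusters - 1))
    u = rng.random(cells)
    cluster = np.where(u < p1, 0, 1 + rng.integers(0, n_clusters - 1, cells))

    genes = truth.gene_ids
    mu = rng.normal(0.0, 1.0, truth.n_genes)
    m5_genes = set(truth.module_defs.get("m5", {}))
    m5_mask = np.array([g in m5_genes for g in genes])
    non_m5 = np.flatnonzero(~m5_mask)
    cluster_boost = np.zeros((n_clusters, truth.n_genes))
    cluster_boost[0, m5_mask] = np.log(m5_factor)
    for cidx in range(1, n_clusters):  # a few private markers per cluster
        marker_genes = rng.choice(non_m5, 10, replace=False)
        cluster_boost[cidx, marker_genes] = np.log(1.5)
    profiles = np.exp(mu[None, :] + cluster_boost)
    profiles /= profiles.sum(axis=1, keepdims=True)
    depth = np.exp(rng.normal(np.log(2500.0), 0.3, cells))
    jitter = np.exp(rng.normal(0.0, 0.25, (cells, truth.n_genes)))
    lam = depth[:, None] * profiles[cluster] * jitter
    counts = rng.poisson(lam)

    import scipy.sparse as sp

    cell_ids = pd.Index([f"C{i:05d}" for i in range(cells)], name="cell_id")
    metadata = pd.DataFrame(
        {
            "subject_id": latents.index.to_numpy()[subject_idx],
            "cluster": [f"Mic{c + 1}" for c in cluster],
        },
        index=cell_ids,
    )
    return SnCountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=pd.Index(genes, name="gene_id"),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# GWAS probe table
# ---------------------------------------------------------------------------

def generate_gwas_summary(
    truth: SyntheticTruth,
    probes_per_gene: int = 5,
    n_ad_genes: int = 12,
    window: int = 50_000,
):
    """Probe p-values and gene intervals with planted susceptibility genes.

    Every planted AD gene gets one probe with p < 0.05 inside the gene +/-
    ``window`` bp (boundaries inclusive); all other probes draw p ~ U(0,1).
    Genes are spaced 250 kb apart so the windows never overlap a neighbor.

    Returns (probes, intervals, ad_genes).
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = truth.rng("gwas")
    genes = truth.gene_ids
    per_chrom = max(1, math.ceil(len(genes) / 22))
    rows, probe_rows = [], []
    for i, gene in enumerate(genes):
        chrom = str(i // per_chrom + 1)
        start = 100_000 + (i % per_chrom) * 250_000
        end = start + int(rng.integers(5_000, 50_000))
        rows.append({"gene_id": gene, "chrom": chrom, "start": start, "end": end})
        for _ in range(probes_per_gene):
            pos = int(rng.integers(max(start - window - 5_000, 1), end + window + 5_000))
            probe_rows.append({"chrom": chrom, "pos": pos, "p": float(rng.uniform(0.0, 1.0))})
    intervals = pd.DataFrame(rows)
    ad_genes = sorted(rng.choice(genes, n_ad_genes, replace=False).tolist())
    lookup = intervals.set_index("gene_id")
    for gene in ad_genes:
        row = lookup.loc[gene]
        probe_rows.append(
            {
                "chrom": row["chrom"],
                "pos": int(rng.integers(row["start"] - window, row["end"] + window + 1)),
                "p": float(rng.uniform(1e-6, 0.0499)),
            }
        )
    probes = pd.DataFrame(probe_rows)
    return probes, intervals, ad_genes
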