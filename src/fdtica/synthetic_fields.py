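"""Synthetic FDT cohorts with archetypal glaucomatous defects, plus an
ICA-mixture sampler used as a recovery oracle.

The generator emulates the statistical shape of a screening cohort: a smooth
normal hill of vision with between-subject and pointwise test noise, and an
abnormal arm built by subtracting severity-scaled defect templates (superior /
inferior altitudinal, superior / inferior nasal steps, their "arrowhead"
union, and diffuse loss).  Defaults are calibrated so that, against the
generator's own normative surface, mean MD is -1.00 dB in the normal arm and
-5.57 dB in the abnormal arm, with ages 50.0 (SD 14.7) vs 55.9 (SD 15.3)
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import stats

from .fields_io import Cohort, FieldRecord, Grid242Layout, N_POINTS, layout_242

ARCHETYPES = (
    "superior_altitudinal",
    "inferior_altitudinal",
    "superior_nasal",
    "inferior_nasal",
    "arrowhead",
    "diffuse",
    "diffuse_superior",
)

#: default mixture over archetypes; altitudinal defects dominate, mirroring
#: the preponderance of altitudinal patterns in clinical FDT clusters
DEFAULT_ARCHETYPE_WEIGHTS = {
    "superior_altitudinal": 0.30,
    "inferior_altitudinal": 0.28,
    "superior_nasal": 0.08,
    "inferior_nasal": 0.08,
    "arrowhead": 0.10,
    "diffuse": 0.10,
    "diffuse_superior": 0.06,
}


def archetype_template(name: str, layout: Optional[Grid242Layout] = None) -> np.ndarray:
    """52-vector of non-positive dB loadings (loss per unit severity).

    Regions follow the layout convention: superior = y > 0, nasal = x > 0
    (right-eye frame).  Altitudinal templates carry a milder diffuse
    component in the opposing hemifield; nasal steps a faint diffuse floor.
    """
    layout = layout or layout_242()
    sup, inf, nas = layout.superior_mask, layout.inferior_mask, layout.nasal_mask
    t = np.zeros(N_POINTS)
    if name == "superior_altitudinal":
        t[sup] = -1.0
        t[inf] = -0.25
    elif name == "inferior_altitudinal":
        t[inf] = -1.0
        t[sup] = -0.25
    elif name == "superior_nasal":
        t[:] = -0.10
        t[sup & nas] = -1.0
    elif name == "inferior_nasal":
        t[:] = -0.10
        t[inf & nas] = -1.0
    elif name == "arrowhead":  # combined superior + inferior nasal step
        t[:] = -0.10
        t[nas] = -1.0
    elif name == "diffuse":
        t[:] = -1.0
    elif name == "diffuse_superior":
        t[sup] = -1.0
        t[inf] = -0.40
    else:
        raise ValueError(f"unknown archetype {name!r}")
    return t


def default_normal_surface(layout: Optional[Grid242Layout] = None) -> np.ndarray:
    """Smooth radial hill of vision, ~30.5 dB centrally declining with eccentricity."""
    layout = layout or layout_242()
    ecc = np.hypot(*layout.coordinates().T)
    return 31.0 - 0.12 * ecc


@dataclass
class GeneratorParams:
    """Tunable cohort-generation parameters (see docs/methods.md for rationale)."""

    normal_mean_surface: np.ndarray = dc_field(default_factory=default_normal_surface)
    md_offset: float = -1.0          # study normals sit 1 dB below the normative surface
    subject_sd: float = 2.75         # dB, between-eye global sensitivity spread
    point_noise_sd: float = 2.0      # dB, iid per-point test noise
    age_normal: tuple[float, float] = (50.0, 14.7)
    age_abnormal: tuple[float, float] = (55.9, 15.3)
    age_bounds: tuple[float, float] = (18.0, 95.0)
    archetype_weights: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_WEIGHTS)
    )
    severity_shape: float = 2.0      # gamma shape of per-eye defect severity
    abnormal_md_drop: float = 4.57   # dB of extra mean MD loss in the abnormal arm
    reliability_means: tuple[float, float, float] = (0.0286, 0.0551, 0.0161)

    def __post_init__(self) -> None:
        self.normal_mean_surface = np.asarray(self.normal_mean_surface, dtype=float)
        if self.normal_mean_surface.shape != (N_POINTS,):
            raise ValueError("normal_mean_surface must be a 52-vector")
        if self.subject_sd <= 0 or self.point_noise_sd < 0:
            raise ValueError("noise SDs must be positive")
        w = np.array(list(self.archetype_weights.values()))
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("archetype weights must be a probability vector")
        for name in self.archetype_weights:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}")

    def severity_scales(self) -> dict[str, float]:
        """Gamma scale per archetype so each contributes abnormal_md_drop in mean MD.

        E[severity] * |mean(template)| = abnormal_md_drop, with
        E[severity] = shape * scale; solved in closed form.
        """
        scales = {}
        for name in self.archetype_weights:
            mean_loss = abs(archetype_template(name).mean())
            scales[name] = self.abnormal_md_drop / (self.severity_shape * mean_loss)
        return scales


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _truncated_ages(rng, mean, sd, bounds, n) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _reliability(rng, params, n) -> np.ndarray:
    # Beta(1, b) with b set by the target mean rate; values capped at the
    # 0.33 reliability criterion so generated cohorts are all "reliable"
    cols = []
    for mean in params.reliability_means:
        b = 1.0 / mean - 1.0
        cols.append(np.minimum(rng.beta(1.0, b, size=n), 0.33))
    return np.column_stack(cols)


def _normal_threshold_block(rng, params, n) -> np.ndarray:
    offs = params.md_offset + rng.normal(0.0, params.subject_sd, size=n)
    noise = rng.normal(0.0, params.point_noise_sd, size=(n, N_POINTS))
    return params.normal_mean_surface[None, :] + offs[:, None] + noise


def generate_normal_fields(n: int, params: Optional[GeneratorParams] = None,
                           rng_seed=0) -> Cohort:
    """n FDT-normal eyes: hill of vision + subject offset + point noise, >= 0 dB."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    params = params or GeneratorParams()
    rng = _rng(rng_seed)
    thr = np.clip(_normal_threshold_block(rng, params, n), 0.0, None)
    ages = _truncated_ages(rng, *params.age_normal, params.age_bounds, n)
    rel = _reliability(rng, params, n)
    eyes = rng.choice(["right", "left"], size=n)
    records = [
        FieldRecord(
            subject_id=f"N{i:05d}", eye=eyes[i], thresholds=thr[i], age=float(ages[i]),
            fp_rate=float(rel[i, 0]), fl_rate=float(rel[i, 1]), fn_rate=float(rel[i, 2]),
            fdt_label="normal",
        )
        for i in range(n)
    ]
    return Cohort(layout=layout_242(), records=records, provenance="synthetic")


def generate_glaucoma_fields(n: int, params: Optional[GeneratorParams] = None,
                             rng_seed=0) -> Cohort:
    """n FDT-abnormal eyes: the normal model minus severity x archetype template."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    params = params or GeneratorParams()
    rng = _rng(rng_seed)
    names = list(params.archetype_weights)
    weights = np.array([params.archetype_weights[a] for a in names])
    scales = params.severity_scales()
    templates = np.stack([archetype_template(a) for a in names])

    base = _normal_threshold_block(rng, params, n)
    which = rng.choice(len(names), size=n, p=weights)
    sev = np.array([rng.gamma(params.severity_shape, scales[names[k]]) for k in which])
    thr = np.clip(base + sev[:, None] * templates[which], 0.0, None)

    ages = _truncated_ages(rng, *params.age_abnormal, params.age_bounds, n)
    rel = _reliability(rng, params, n)
    eyes = rng.choice(["right", "left"], size=n)
    records = [
        FieldRecord(
            subject_id=f"G{i:05d}", eye=eyes[i], thresholds=thr[i], age=float(ages[i]),
            fp_rate=float(rel[i, 0]), fl_rate=float(rel[i, 1]), fn_rate=float(rel[i, 2]),
            fdt_label="abnormal", archetype=names[which[i]], severity=float(sev[i]),
        )
        for i in range(n)
    ]
    return Cohort(layout=layout_242(), records=records, provenance="synthetic")


def generate_study_cohort(n_normal: int = 1190, n_abnormal: int = 786,
                          params: Optional[GeneratorParams] = None,
                          seed=0) -> Cohort:
    """Concatenated, shuffled normal + abnormal cohorts (defaults: 1,190 + 786)."""
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    s_norm, s_abn, s_shuf = ss.spawn(3)
    parts: list[FieldRecord] = []
    if n_normal > 0:
        parts += generate_normal_fields(n_normal, params, np.random.default_rng(s_norm)).records
    if n_abnormal > 0:
        parts += generate_glaucoma_fields(n_abnormal, params, np.random.default_rng(s_abn)).records
    if not parts:
        raise ValueError("cohort would be empty")
    order = np.random.default_rng(s_shuf).permutation(len(parts))
    return Cohort(layout=layout_242(), records=[parts[i] for i in order],
                  provenance="synthetic")


@dataclass
class GroundTruthICAMixture:
    """Known mixture-of-ICA generative model for recovery oracles.

    K clusters sharing a source dimension L with m Gaussian components per
    source; observation = mean + mixing @ sources + diagonal Gaussian noise.
    """

    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, D)
    mixing: np.ndarray           # (K, D, L)
    source_weights: np.ndarray   # (K, L, m)
    source_means: np.ndarray     # (K, L, m)
    source_sds: np.ndarray       # (K, L, m)
    noise_sd: np.ndarray         # (K, D)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.mixing = np.asarray(self.mixing, float)
        self.source_weights = np.asarray(self.source_weights, float)
        self.source_means = np.asarray(self.source_means, float)
        self.source_sds = np.asarray(self.source_sds, float)
        self.noise_sd = np.atleast_2d(np.asarray(self.noise_sd, float))
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("cluster weights must sum to 1")
        K, D, L = self.mixing.shape
        for k in range(K):
            if np.linalg.matrix_rank(self.mixing[k]) < L:
                raise ValueError(f"mixing matrix of cluster {k} is rank deficient")
        if not np.allclose(self.source_weights.sum(axis=-1), 1.0):
            raise ValueError("source component weights must sum to 1")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        K, D, L = self.mixing.shape
        return K, D, L, self.source_weights.shape[-1]


def sample_ica_mixture(truth: GroundTruthICAMixture, n: int, seed=0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n observations; returns (X (n,D), cluster labels (n,), sources (n,L))."""
    rng = _rng(seed)
    K, D, L, m = truth.shape
    z = rng.choice(K, size=n, p=truth.weights)
    S = np.zeros((n, L))
    X = np.zeros((n, D))
    for k in range(K):
        idx = np.flatnonzero(z == k)
        if idx.size == 0:
            continue
        for l in range(L):
            comp = rng.choice(m, size=idx.size, p=truth.source_weights[k, l])
            S[idx, l] = (truth.source_means[k, l, comp]
                         + truth.source_sds[k, l, comp] * rng.standard_normal(idx.size))
        X[idx] = (truth.means[k][None, :]
                  + S[idx] @ truth.mixing[k].T
                  + truth.noise_sd[k][None, :] * rng.standard_normal((idx.size, D)))
    return X, z, S
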