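"""Synthetic multi-omics case/control cohort generation.

Real multi-omics Parkinson's cohorts (genotype dosages + whole-blood
expression + clinico-demographics) are access-controlled, so this module
provides a liability-threshold generative model that emulates their
*structure*: a genetic block of biallelic dosages with a polygenic risk
score, a transcriptomic block confounded by latent population substructure,
a small clinical block, and an optional distribution-shifted external cohort.
Every downstream stage of the pipeline (preprocessing, partitioning,
federated training, evaluation) is exercised against these cohorts with
known ground truth.

The generative model is this package's own construction — it is
parameterized, documented in ``docs/methods.md``, and makes no claim to
reproduce any particular real cohort beyond its shape and difficulty.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CohortSpec",
    "FeatureMatrix",
    "GroundTruth",
    "RejectionSamplingError",
    "generate_cohort",
    "generate_linked_cohorts",
]

GROUP_GENETIC = "genetic"
GROUP_PRS = "prs"
GROUP_TRANSCRIPTOMIC = "transcriptomic"
GROUP_CLINICAL = "clinical"
VALID_GROUPS = (GROUP_GENETIC, GROUP_PRS, GROUP_TRANSCRIPTOMIC, GROUP_CLINICAL)

# Candidate draws allowed per requested sample before the generator gives up.
REJECTION_CAP_FACTOR = 500
_CALIBRATION_POOL = 4000

_CLINICAL_NAMES = ("AGE", "SEX", "FAMILY_HISTORY", "UPSIT_SCORE", "EDUCATION_YEARS")


class RejectionSamplingError(RuntimeError):
    """Raised when case/control rejection sampling exhausts its draw cap."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generative model.

    Defaults mirror the emulated study design: a 171-case / 427-control
    training cohort geometry with 673 features per sample (71 SNP dosages +
    1 polygenic risk score, 596 expression features, 5 clinico-demographic
    features).  Effect-size scales were fixed once, by Monte-Carlo
    calibration, to put a regularized linear classifier at a realistic
    (non-saturated) AUC-PR operating point around 0.85-0.95.
    """

    n_cases: int
    n_controls: int
    n_snp: int = 71
    n_expr: int = 596
    n_clin: int = 5
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal_snp: int | None = None  # default resolves to min(20, n_snp)
    beta_scale_genetic: float = 0.8
    beta_scale_expr: float = 0.02
    beta_scale_clin: float = 0.6
    expr_disease_loading: float = 0.5
    confound_strength: float = 0.5
    noise_sd: float = 0.8
    shift_effect_scale: float = 1.0
    shift_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_snp is None:
            object.__setattr__(self, "n_causal_snp", min(20, self.n_snp))
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must each be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal_snp > self.n_snp:
            raise ValueError("n_causal_snp cannot exceed n_snp")
        for name in (
            "beta_scale_genetic",
            "beta_scale_expr",
            "beta_scale_clin",
            "expr_disease_loading",
            "confound_strength",
            "noise_sd",
            "shift_effect_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_features(self) -> int:
        return self.n_snp + 1 + self.n_expr + self.n_clin

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FeatureMatrix:
    """Samples x features table with binary phenotype labels.

    The universal currency of the pipeline.  ``values`` is a dense float
    matrix; ``feature_groups`` tags every column with one of
    ``{genetic, prs, transcriptomic, clinical}``.
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    values: np.ndarray
    feature_names: np.ndarray
    feature_groups: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.feature_groups = np.asarray(self.feature_groups, dtype=object)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must match row count")
        if len(self.feature_names) != p or len(self.feature_groups) != p:
            raise ValueError("feature names/groups length must match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature identifiers")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        unknown = set(self.feature_groups) - set(VALID_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.labels.sum())

    def group_mask(self, *groups: str) -> np.ndarray:
        return np.isin(self.feature_groups, list(groups))

    def group_columns(self, *groups: str) -> np.ndarray:
        return np.flatnonzero(self.group_mask(*groups))

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, index) -> "FeatureMatrix":
        """Row subset by positional index array or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return FeatureMatrix(
            sample_ids=self.sample_ids[index],
            labels=self.labels[index],
            values=self.values[index],
            feature_names=self.feature_names,
            feature_groups=self.feature_groups,
        )

    def subset_by_ids(self, ids) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            index = np.array([pos[s] for s in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc
        return self.subset_samples(index)

    def subset_features(self, names) -> "FeatureMatrix":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        cols = np.array([pos[f] for f in names], dtype=np.int64)
        return FeatureMatrix(
            sample_ids=self.sample_ids,
            labels=self.labels,
            values=self.values[:, cols],
            feature_names=self.feature_names[cols],
            feature_groups=self.feature_groups[cols],
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            sample_ids=self.sample_ids.copy(),
            labels=self.labels.copy(),
            values=self.values.copy(),
            feature_names=self.feature_names.copy(),
            feature_groups=self.feature_groups.copy(),
        )

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "PHENO", self.labels)
        df.insert(0, "ID", self.sample_ids)
        return df

    def write_tsv(self, path) -> None:
        """Write as tab-separated text: ID, PHENO, then feature columns,
        plus a ``<stem>.groups.tsv`` sidecar mapping feature -> group."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = path.with_suffix(".groups.tsv")
        pd.DataFrame(
            {"feature": list(self.feature_names), "group": list(self.feature_groups)}
        ).to_csv(sidecar, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        groups = pd.read_csv(path.with_suffix(".groups.tsv"), sep="\t")
        group_of = dict(zip(groups["feature"], groups["group"]))
        feature_names = [c for c in df.columns if c not in ("ID", "PHENO")]
        return cls(
            sample_ids=df["ID"].astype(str).to_numpy(dtype=object),
            labels=df["PHENO"].to_numpy(),
            values=df[feature_names].to_numpy(dtype=np.float64),
            feature_names=np.array(feature_names, dtype=object),
            feature_groups=np.array(
                [group_of[f] for f in feature_names], dtype=object
            ),
        )


@dataclass
class GroundTruth:
    """True generative parameters and realized latents for one cohort."""

    maf: np.ndarray
    beta_genetic: np.ndarray
    beta_expr: np.ndarray
    beta_clin: np.ndarray
    causal_snp_index: np.ndarray
    expr_confound_weights: np.ndarray
    expr_disease_weights: np.ndarray
    ancestry_factor: np.ndarray
    liability: np.ndarray
    threshold: float
    prs_mean: float
    prs_sd: float

    def write_tsv(self, path) -> None:
        path = Path(path)
        coef = pd.DataFrame(
            {
                "block": (
                    ["genetic"] * len(self.beta_genetic)
                    + ["transcriptomic"] * len(self.beta_expr)
                    + ["clinical"] * len(self.beta_clin)
                ),
                "beta": np.concatenate(
                    [self.beta_genetic, self.beta_expr, self.beta_clin]
                ),
            }
        )
        coef.to_csv(path, sep="\t", index=False, float_format="%.10g")
        per_sample = pd.DataFrame(
            {"ancestry_factor": self.ancestry_factor, "liability": self.liability}
        )
        per_sample.to_csv(
            Path(path).with_suffix(".samples.tsv"),
            sep="\t",
            index=False,
            float_format="%.10g",
        )


# ---------------------------------------------------------------------------
# generative machinery
# ---------------------------------------------------------------------------


@dataclass
class _Truth:
    """Shared generative truth (drawn once, reused across linked cohorts)."""

    maf: np.ndarray
    beta_genetic: np.ndarray
    beta_expr: np.ndarray
    beta_clin: np.ndarray
    causal_snp_index: np.ndarray
    expr_confound_weights: np.ndarray
    expr_disease_weights: np.ndarray


def _draw_truth(spec: CohortSpec, rng: np.random.Generator) -> _Truth:
    maf = rng.uniform(spec.maf_low, spec.maf_high, size=spec.n_snp)
    causal = np.sort(rng.choice(spec.n_snp, size=spec.n_causal_snp, replace=False))
    beta_g = np.zeros(spec.n_snp)
    beta_g[causal] = rng.normal(0.0, spec.beta_scale_genetic, size=spec.n_causal_snp)
    beta_e = rng.normal(0.0, spec.beta_scale_expr, size=spec.n_expr)
    w_conf = rng.normal(0.0, 1.0, size=spec.n_expr)
    w_dis = rng.normal(0.0, spec.expr_disease_loading, size=spec.n_expr)
    beta_c = rng.normal(0.0, spec.beta_scale_clin, size=spec.n_clin)
    # the smell-test feature is a strong *protective*-direction covariate:
    # lower scores mean higher liability
    if spec.n_clin >= 4:
        beta_c[3] = -abs(beta_c[3])
    return _Truth(maf, beta_g, beta_e, beta_c, causal, w_conf, w_dis)


def _draw_candidates(
    spec: CohortSpec,
    truth: _Truth,
    rng: np.random.Generator,
    m: int,
    effect_scale: float,
    lg_mean: float,
    lg_sd: float,
):
    """Draw m candidate samples; returns raw blocks + liabilities.

    ``lg_mean``/``lg_sd`` standardize the genetic liability contribution
    before it loads onto expression (estimated from the calibration pool).
    """
    ancestry = rng.normal(0.0, 1.0, size=m)
    p = expit(logit(truth.maf)[None, :] + spec.confound_strength * ancestry[:, None])
    geno = rng.binomial(2, p).astype(np.float64)
    lg = geno @ (effect_scale * truth.beta_genetic)
    lg_std = (lg - lg_mean) / lg_sd

    expr = (
        spec.confound_strength * ancestry[:, None] * truth.expr_confound_weights[None, :]
        + lg_std[:, None] * truth.expr_disease_weights[None, :]
        + rng.normal(0.0, 1.0, size=(m, spec.n_expr))
    )

    # clinical latents (standard scale) drive liability; stored features live
    # on natural scales, recovered to z-scale by preprocessing
    n_clin = spec.n_clin
    clin_z = np.zeros((m, n_clin))
    clin_raw = np.zeros((m, n_clin))
    if n_clin >= 1:  # age
        z = rng.normal(0.0, 1.0, size=m)
        clin_z[:, 0] = z
        clin_raw[:, 0] = 61.0 + 10.0 * z
    if n_clin >= 2:  # sex
        x = rng.binomial(1, 0.5, size=m).astype(float)
        clin_z[:, 1] = (x - 0.5) / 0.5
        clin_raw[:, 1] = x
    if n_clin >= 3:  # family history
        x = rng.binomial(1, 0.15, size=m).astype(float)
        clin_z[:, 2] = (x - 0.15) / np.sqrt(0.15 * 0.85)
        clin_raw[:, 2] = x
    if n_clin >= 4:  # smell identification score
        z = rng.normal(0.0, 1.0, size=m)
        clin_z[:, 3] = z
        clin_raw[:, 3] = 25.0 + 8.0 * z
    for j in range(4, n_clin):  # extra continuous covariates
        z = rng.normal(0.0, 1.0, size=m)
        clin_z[:, j] = z
        clin_raw[:, j] = z

    liability = (
        lg
        + expr @ (effect_scale * truth.beta_expr)
        + clin_z @ (effect_scale * truth.beta_clin)
        + rng.normal(0.0, spec.noise_sd, size=m)
    )
    return ancestry, geno, lg, expr, clin_raw, liability


def _calibrate(
    spec: CohortSpec, truth: _Truth, rng: np.random.Generator, effect_scale: float
):
    """Estimate PRS standardization and the case threshold from a fixed pool.

    Pool-based (rather than cohort-based) statistics keep the feature
    definition independent of the requested cohort size and shared across
    linked cohorts.
    """
    m = _CALIBRATION_POOL
    ancestry = rng.normal(0.0, 1.0, size=m)
    p = expit(logit(truth.maf)[None, :] + spec.confound_strength * ancestry[:, None])
    geno = rng.binomial(2, p).astype(np.float64)
    lg_raw = geno @ truth.beta_genetic  # unscaled: PRS is a fixed feature map
    prs_mean = float(lg_raw.mean())
    prs_sd = float(lg_raw.std())
    if prs_sd < 1e-12:
        prs_sd = 1.0

    lg_eff = geno @ (effect_scale * truth.beta_genetic)
    lg_mean, lg_sd = float(lg_eff.mean()), float(lg_eff.std())
    if lg_sd < 1e-12:
        lg_sd = 1.0
    lg_std = (lg_eff - lg_mean) / lg_sd

    expr = (
        spec.confound_strength * ancestry[:, None] * truth.expr_confound_weights[None, :]
        + lg_std[:, None] * truth.expr_disease_weights[None, :]
        + rng.normal(0.0, 1.0, size=(m, spec.n_expr))
    )
    clin_z = rng.normal(0.0, 1.0, size=(m, spec.n_clin))
    liability = (
        lg_eff
        + expr @ (effect_scale * truth.beta_expr)
        + clin_z @ (effect_scale * truth.beta_clin)
        + rng.normal(0.0, spec.noise_sd, size=m)
    )
    target_prev = spec.n_cases / spec.n_samples
    threshold = float(np.quantile(liability, 1.0 - target_prev))
    return prs_mean, prs_sd, lg_mean, lg_sd, threshold


def _feature_names(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    names = (
        [f"SNP_{j + 1:04d}" for j in range(spec.n_snp)]
        + ["PRS"]
        + [f"GENE_{k + 1:04d}" for k in range(spec.n_expr)]
        + [
            _CLINICAL_NAMES[j] if j < len(_CLINICAL_NAMES) else f"CLIN_{j + 1}"
            for j in range(spec.n_clin)
        ]
    )
    groups = (
        [GROUP_GENETIC] * spec.n_snp
        + [GROUP_PRS]
        + [GROUP_TRANSCRIPTOMIC] * spec.n_expr
        + [GROUP_CLINICAL] * spec.n_clin
    )
    return np.array(names, dtype=object), np.array(groups, dtype=object)


def _generate_with_truth(
    spec: CohortSpec,
    truth: _Truth,
    salt: int,
    effect_scale: float,
    shift_mean: float,
    prs_params: tuple[float, float] | None,
    id_prefix: str,
) -> tuple[FeatureMatrix, GroundTruth]:
    ss = np.random.SeedSequence([int(spec.seed), salt])
    cal_seq, sample_seq = ss.spawn(2)
    cal_rng = np.random.default_rng(cal_seq)
    prs_mean_c, prs_sd_c, lg_mean, lg_sd, threshold = _calibrate(
        spec, truth, cal_rng, effect_scale
    )
    prs_mean, prs_sd = prs_params if prs_params is not None else (prs_mean_c, prs_sd_c)

    rng = np.random.default_rng(sample_seq)
    need_cases, need_controls = spec.n_cases, spec.n_controls
    cap = REJECTION_CAP_FACTOR * spec.n_samples
    drawn = 0
    kept: list[tuple] = []  # (ancestry, geno, lg_raw_unscaled, expr, clin, L, label)
    batch = max(256, spec.n_samples)
    while need_cases > 0 or need_controls > 0:
        m = min(batch, cap - drawn)
        if m <= 0:
            raise RejectionSamplingError(
                f"rejection sampling exceeded the cap of {cap} candidate draws "
                f"({REJECTION_CAP_FACTOR} x cohort size); the spec is likely "
                "infeasible (e.g. zero effects with a degenerate threshold)"
            )
        ancestry, geno, _lg, expr, clin, liab = _draw_candidates(
            spec, truth, rng, m, effect_scale, lg_mean, lg_sd
        )
        drawn += m
        is_case = liab > threshold
        for i in range(m):
            if is_case[i] and need_cases > 0:
                kept.append((ancestry[i], geno[i], expr[i], clin[i], liab[i], 1))
                need_cases -= 1
            elif not is_case[i] and need_controls > 0:
                kept.append((ancestry[i], geno[i], expr[i], clin[i], liab[i], 0))
                need_controls -= 1
            if need_cases == 0 and need_controls == 0:
                break

    ancestry = np.array([k[0] for k in kept])
    geno = np.stack([k[1] for k in kept])
    expr = np.stack([k[2] for k in kept])
    clin = np.stack([k[3] for k in kept])
    liability = np.array([k[4] for k in kept])
    labels = np.array([k[5] for k in kept], dtype=np.int64)

    prs = (geno @ truth.beta_genetic - prs_mean) / prs_sd
    expr_stored = expr + shift_mean
    values = np.concatenate(
        [geno, prs[:, None], expr_stored, clin], axis=1
    )
    names, groups = _feature_names(spec)
    matrix = FeatureMatrix(
        sample_ids=np.array(
            [f"{id_prefix}{i + 1:05d}" for i in range(spec.n_samples)], dtype=object
        ),
        labels=labels,
        values=values,
        feature_names=names,
        feature_groups=groups,
    )
    gt = GroundTruth(
        maf=truth.maf.copy(),
        beta_genetic=effect_scale * truth.beta_genetic,
        beta_expr=effect_scale * truth.beta_expr,
        beta_clin=effect_scale * truth.beta_clin,
        causal_snp_index=truth.causal_snp_index.copy(),
        expr_confound_weights=truth.expr_confound_weights.copy(),
        expr_disease_weights=truth.expr_disease_weights.copy(),
        ancestry_factor=ancestry,
        liability=liability,
        threshold=threshold,
        prs_mean=prs_mean,
        prs_sd=prs_sd,
    )
    return matrix, gt


def generate_cohort(spec: CohortSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Generate one case/control cohort under the liability-threshold model.

    Per sample: a latent ancestry factor shifts genotype frequencies and
    loads onto expression; liability is the sum of genetic, expression and
    clinical contributions plus Gaussian noise; case status is liability
    above a pool-calibrated threshold; rejection sampling fills exactly
    ``(n_cases, n_controls)``.

    Returns the feature matrix and the generative ground truth.  Raises
    :class:`RejectionSamplingError` when the draw cap
    (``500 x cohort size``) is exhausted.
    """
    truth_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    truth = _draw_truth(spec, truth_rng)
    return _generate_with_truth(
        spec,
        truth,
        salt=1,
        effect_scale=1.0,
        shift_mean=0.0,
        prs_params=None,
        id_prefix="S",
    )


def generate_linked_cohorts(
    internal: CohortSpec, external: CohortSpec
) -> tuple[
    tuple[FeatureMatrix, GroundTruth], tuple[FeatureMatrix, GroundTruth]
]:
    """Generate an internal training cohort plus a shifted external cohort.

    Both cohorts share one generative truth (MAFs, effect vectors, PRS
    standardization) drawn from the *internal* seed.  The external cohort
    attenuates every liability coefficient by ``external.shift_effect_scale``
    and offsets the stored transcriptomic block by ``external.shift_mean`` —
    a covariate/effect-shift analogue of post-treatment artifacts in an
    out-of-distribution validation cohort.
    """
    for attr in ("n_snp", "n_expr", "n_clin"):
        if getattr(internal, attr) != getattr(external, attr):
            raise ValueError(
                f"linked cohorts need identical feature counts; {attr} differs "
                f"({getattr(internal, attr)} vs {getattr(external, attr)})"
            )
    truth_rng = np.random.default_rng(np.random.SeedSequence([int(internal.seed), 0]))
    truth = _draw_truth(internal, truth_rng)
    internal_pair = _generate_with_truth(
        internal,
        truth,
        salt=1,
        effect_scale=1.0,
        shift_mean=0.0,
        prs_params=None,
        id_prefix="INT",
    )
    prs_params = (internal_pair[1].prs_mean, internal_pair[1].prs_sd)
    external_pair = _generate_with_truth(
        external,
        truth,
        salt=2,
        effect_scale=external.shift_effect_scale,
        shift_mean=external.shift_mean,
        prs_params=prs_params,
        id_prefix="EXT",
    )
    return internal_pair, external_pair
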