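"""Synthetic-data generator emulating the study design, with known ground truth.

Every pipeline input can be generated here: a paired profiling Ct matrix
(3 matched case/control serum pairs on a 752-assay miRNA panel, roughly half
the assays censoring at Ct 40), a validation cohort (31 metastasis vs 52
non-metastasis samples with binormal group separation calibrated to a target
AUC), right-censored progression-free-survival times driven by true
biomarker positivity, paired tumour/adjacent tissue expression, and
cell-line/culture-medium replicates.

Generative model on the Ct scale (cycles; lower Ct = more template):

*Profiling pairs.*  Ct(a, pair member) = mu_a + b_{a,pair} + plate_offset
- log2FC_a * [case] + eps, with a biological effect b_{a,pair} ~
N(0, sigma_pair) shared by both members of a matched pair (it cancels in the
delta-delta-Ct, which is the point of pairing) and technical noise
eps ~ N(0, sigma_ct).  Filler panel assays fall in three abundance classes:
abundant (mean Ct 26-34, always detected), borderline (mean Ct ~
N(censor_ct + 0.15, sigma_pair), spreading the per-pair detection
probability over (0, 1)) and absent (mean Ct >> censor_ct).  The small
+0.15 offset compensates the smoothing of the censor boundary by technical
noise (a pair is excluded only when *both* members censor); with 177
abundant and 371 borderline assays of 752 the expected per-pair detected
count is 177 + 371 * 0.505 = 364 and the expected three-pair intersection
is 177 + 371 * 0.249 = 269, the scale of the emulated screen.

*Validation cohort.*  Ct(a, s) = mu_a + c_{a,s} + plate_offset - delta_a *
[metastasis] + eps with independent per-patient biological variation
c_{a,s} ~ N(0, sd_a).  Reference assays get sd_a chosen so their
across-sample SD (hence CV%) matches the configured target; the group shift
delta_a is calibrated through the binormal identity
AUC = Phi(delta / (s * sqrt(2))) with s the per-sample dCt SD, so the
expected empirical AUC equals the configured target.

Censoring is by thresholding the latent Ct at ``censor_ct`` (left-censoring
of expression), not dropout at random.  The same seed and config produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .discovery_screen import PairDesign
from .errors import ConfigError
from .qpcr_io import GROUP_METASTASIS, GROUP_NON_METASTASIS, CtMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_profiling_pairs",
    "simulate_validation_cohort",
    "simulate_paired_tissue",
    "simulate_cell_medium",
    "write_all_inputs",
    "TABLE_FOLD_CHANGES",
]

#: consensus screen hits being emulated: assay -> (avg FC vs miR-16-5p, vs miR-93-5p)
TABLE_FOLD_CHANGES: dict[str, tuple[float, float]] = {
    "hsa-let-7c-5p": (6.936, 2.569),
    "hsa-let-7d-5p": (4.521, 2.360),
    "hsa-let-7e-5p": (3.619, 1.940),
    "hsa-miR-144-5p": (4.656, 2.802),
    "hsa-miR-186-5p": (4.667, 1.800),
    "hsa-miR-20b-5p": (69.990, 12.134),
    "hsa-miR-331-3p": (32.978, 20.656),
    "hsa-miR-379-5p": (127.829, 49.628),
    "hsa-miR-410-3p": (321.130, 103.873),
    "hsa-miR-495-3p": (24.731, 41.811),
    "hsa-miR-532-5p": (3.466, 1.727),
    "hsa-miR-98-5p": (5.873, 2.369),
    "hsa-miR-99b-5p": (3.824, 1.651),
    "hsa-miR-450a-5p": (0.516, 0.347),
    "hsa-miR-450b-5p": (0.006, 0.005),
    "hsa-miR-505-5p": (0.141, 0.041),
    "hsa-miR-589-5p": (0.242, 0.316),
    "hsa-miR-603": (0.187, 0.140),
    "hsa-miR-934": (0.346, 0.230),
}

DEFAULT_BIOMARKER_LOG2FC: dict[str, float] = {
    a: float(np.log2(fc16)) for a, (fc16, _) in TABLE_FOLD_CHANGES.items()
}

#: validation-phase shortlist (user-supplied candidates in a real run)
DEFAULT_VALIDATION_ASSAYS = (
    "hsa-let-7c-5p",
    "hsa-miR-144-5p",
    "hsa-miR-379-5p",
    "hsa-miR-410-3p",
    "hsa-miR-98-5p",
    "hsa-miR-505-5p",
    "hsa-miR-934",
)

_SPIKEIN_MEANS = {
    "UniSp2": 19.0,
    "UniSp4": 24.0,
    "UniSp5": 29.0,
    "UniSp6": 18.0,
    "cel-miR-39-5p": 20.0,
    "UniSp3": 21.0,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_assays: int = 752  # endogenous targets on the panel, references included
    n_pairs: int = 3
    n_validation_met: int = 31
    n_validation_non: int = 52
    censor_ct: float = 40.0
    sigma_ct: float = 0.4  # technical noise, cycles
    sigma_pair: float = 1.3  # pair-level biological effect (profiling), cycles
    sigma_bio: float = 1.0  # per-patient biological SD of target assays, cycles
    sigma_plate: float = 0.15  # plate offset SD, cycles
    sigma_spikein: float = 0.1  # spike-in jitter, cycles
    # abundance classes for filler panel assays (rest is 'absent'); defaults give
    # 177 abundant + 371 borderline of 752 -> E[detected/pair]=364, E[common]=269
    p_abundant: float = 177 / 752
    p_borderline: float = 371 / 752
    # stable references: assay -> (mean Ct, target across-sample SD)
    reference_assays: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hsa-miR-16-5p": (23.258, 1.424),
            "hsa-miR-93-5p": (28.194, 1.466),
        }
    )
    # candidates that fail full detection in the cohort: assay -> mean Ct near 40
    failed_reference_assays: dict[str, float] = field(
        default_factory=lambda: {"hsa-miR-486-3p": 39.8, "SNORD38B": 40.6}
    )
    # planted case/control log2 fold changes for the profiling screen
    biomarker_log2fc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_LOG2FC)
    )
    # validation cohort: assay -> target AUC (binormal); others sit at 0.5
    validation_assays: tuple[str, ...] = DEFAULT_VALIDATION_ASSAYS
    validation_auc: dict[str, float] = field(
        default_factory=lambda: {"hsa-miR-379-5p": 0.70, "hsa-miR-410-3p": 0.70}
    )
    # survival: exponential baseline, HR for true-biomarker-positive patients
    baseline_hazard: float = 0.005  # per month
    hazard_ratio: float = 3.0
    followup_months: float = 60.0
    # paired tissue
    tissue_n_pairs: int = 43
    tissue_down_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "hsa-miR-379-5p": 32 / 43,
            "hsa-miR-410-3p": 33 / 43,
        }
    )
    tissue_effect_log2: float = 1.0
    n_replicates_cellline: int = 3

    def __post_init__(self):
        for name, r in (
            ("p_abundant", self.p_abundant),
            ("p_borderline", self.p_borderline),
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if self.p_abundant + self.p_borderline > 1.0:
            raise ConfigError("abundance class proportions exceed 1")
        for a, auc in self.validation_auc.items():
            if not 0.5 <= auc < 1.0:
                raise ConfigError(f"target AUC for {a!r} must be in [0.5, 1), got {auc}")
        for a, f in self.tissue_down_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"tissue down fraction for {a!r} must be in [0, 1]")
        if not all(np.isfinite(list(self.biomarker_log2fc.values()) or [0.0])):
            raise ConfigError("biomarker shifts must be finite")
        n_named = (
            len(self.biomarker_log2fc)
            + len(self.reference_assays)
            + len(self.failed_reference_assays)
        )
        if self.n_assays < n_named:
            raise ConfigError(
                f"n_assays={self.n_assays} smaller than the {n_named} named assays"
            )

    def reference_bio_sd(self, assay: str) -> float:
        """Biological SD for a reference so its total across-sample SD matches
        the configured target."""
        _, target_sd = self.reference_assays[assay]
        return float(np.sqrt(max(target_sd**2 - self.sigma_ct**2, 0.0)))


@dataclass
class SimulationTruth:
    """Ground-truth manifest for parameter-recovery tests."""

    references: list[str]
    biomarker_log2fc: dict[str, float]
    validation_auc: dict[str, float]
    hazard_ratio: float
    tissue_down_fraction: dict[str, float]
    positive_true: dict[str, bool] = field(default_factory=dict)

    @property
    def up_assays(self) -> list[str]:
        return [a for a, d in self.biomarker_log2fc.items() if d > 0]

    @property
    def down_assays(self) -> list[str]:
        return [a for a, d in self.biomarker_log2fc.items() if d < 0]

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _make_truth(cfg: SimulationConfig) -> SimulationTruth:
    return SimulationTruth(
        references=list(cfg.reference_assays),
        biomarker_log2fc=dict(cfg.biomarker_log2fc),
        validation_auc=dict(cfg.validation_auc),
        hazard_ratio=cfg.hazard_ratio,
        tissue_down_fraction=dict(cfg.tissue_down_fraction),
    )


def _filler_means(cfg: SimulationConfig, n_filler: int, rng) -> np.ndarray:
    """Baseline mean Ct for unnamed panel assays across abundance classes."""
    n_named_abundant = len(cfg.biomarker_log2fc) + len(cfg.reference_assays)
    n_abundant = max(int(round(cfg.p_abundant * cfg.n_assays)) - n_named_abundant, 0)
    n_borderline = max(
        int(round(cfg.p_borderline * cfg.n_assays)) - len(cfg.failed_reference_assays),
        0,
    )
    if n_abundant + n_borderline > n_filler:
        raise ConfigError("infeasible abundance proportions for n_assays")
    n_absent = n_filler - n_abundant - n_borderline
    mu = np.concatenate(
        [
            rng.uniform(26.0, 34.0, n_abundant),
            rng.normal(cfg.censor_ct + 0.15, cfg.sigma_pair, n_borderline),
            rng.uniform(44.0, 48.0, n_absent),
        ]
    )
    rng.shuffle(mu)
    return mu


def _panel_profile(cfg: SimulationConfig, rng) -> tuple[pd.Series, pd.Series]:
    """(mean Ct, biological SD) for every endogenous panel assay."""
    mu: dict[str, float] = {}
    bio: dict[str, float] = {}
    for a in cfg.reference_assays:
        mu[a] = cfg.reference_assays[a][0]
        bio[a] = cfg.reference_bio_sd(a)
    for a, mean in cfg.failed_reference_assays.items():
        mu[a] = mean
        bio[a] = cfg.sigma_pair
    for a in cfg.biomarker_log2fc:
        mu[a] = float(rng.uniform(26.0, 30.0))
        bio[a] = cfg.sigma_pair
    for i, m in enumerate(_filler_means(cfg, cfg.n_assays - len(mu), rng)):
        name = f"hsa-miR-sim-{i + 1:04d}"
        mu[name] = float(m)
        bio[name] = cfg.sigma_pair
    return pd.Series(mu), pd.Series(bio)


def _finish_matrix(
    cfg: SimulationConfig,
    ct: np.ndarray,
    assays: list[str],
    sample_ids: list[str],
    plate_of_sample: dict[str, str],
    rng,
) -> CtMatrix:
    """Add plate offsets and spike-in rows, censor at the threshold."""
    plates = sorted(set(plate_of_sample.values()))
    plate_off = dict(zip(plates, rng.normal(0.0, cfg.sigma_plate, len(plates))))
    off = np.array([plate_off[plate_of_sample[s]] for s in sample_ids])
    ct = ct + off[None, :]
    spike_ids = list(_SPIKEIN_MEANS)
    spike_ct = (
        np.array([_SPIKEIN_MEANS[a] for a in spike_ids])[:, None]
        + rng.normal(0.0, cfg.sigma_spikein, (len(spike_ids), len(sample_ids)))
        + off[None, :]
    )
    all_ids = assays + spike_ids
    full = np.vstack([ct, spike_ct])
    censored = full > cfg.censor_ct
    censored[len(assays) :, :] = False  # spike-ins added at known amounts
    m = CtMatrix(
        ct=pd.DataFrame(full, index=all_ids, columns=sample_ids),
        censored=pd.DataFrame(censored, index=all_ids, columns=sample_ids),
        plate_of_sample=dict(plate_of_sample),
    )
    m.validate()
    return m


def simulate_profiling_pairs(
    cfg: SimulationConfig,
) -> tuple[CtMatrix, list[PairDesign], SimulationTruth]:
    """Paired profiling panel: ``n_pairs`` matched case/control samples over
    ``n_assays`` endogenous assays plus spike-ins, one plate per pair.

    Planted biomarkers shift the case Ct by -log2FC; with zero noise and zero
    shifts every pair fold change is exactly 1.
    """
    rng = _rng(cfg, 1)
    mu, bio = _panel_profile(cfg, rng)
    assays = list(mu.index)

    sample_ids: list[str] = []
    plate_of_sample: dict[str, str] = {}
    pairs: list[PairDesign] = []
    for p in range(1, cfg.n_pairs + 1):
        case, ctrl = f"pair{p}_met", f"pair{p}_non"
        sample_ids += [case, ctrl]
        plate_of_sample[case] = plate_of_sample[ctrl] = f"plate{p}"
        pairs.append(PairDesign(f"pair{p}", case, ctrl))

    # pair-level biological effect, shared by both members (cancels in ddCt)
    b = rng.normal(0.0, 1.0, (len(assays), cfg.n_pairs)) * bio.to_numpy()[:, None]
    b_cols = np.repeat(b, 2, axis=1)  # columns ordered case, control per pair
    shifts = np.zeros((len(assays), len(sample_ids)))
    case_cols = [2 * i for i in range(cfg.n_pairs)]
    for a, d in cfg.biomarker_log2fc.items():
        shifts[assays.index(a), case_cols] = -d  # lower Ct = higher expression
    eps = rng.normal(0.0, cfg.sigma_ct, (len(assays), len(sample_ids)))
    ct = mu.to_numpy()[:, None] + b_cols + shifts + eps
    m = _finish_matrix(cfg, ct, assays, sample_ids, plate_of_sample, rng)
    return m, pairs, _make_truth(cfg)


def _sample_clinical(cfg: SimulationConfig, sample_ids, groups, rng) -> pd.DataFrame:
    """Stage/gender/age margins near the emulated cohort; stage is mildly
    associated with metastasis, other covariates are independent of the
    biomarkers."""
    stage_p = {
        GROUP_METASTASIS: np.array([11, 8, 15]) / 34.0,
        GROUP_NON_METASTASIS: np.array([22, 22, 11]) / 55.0,
    }
    male_p = {GROUP_METASTASIS: 19 / 34.0, GROUP_NON_METASTASIS: 36 / 55.0}
    age_mean = {GROUP_METASTASIS: 67.5, GROUP_NON_METASTASIS: 61.9}
    rows = []
    for s, g in zip(sample_ids, groups):
        stage = rng.choice(["II", "IIIA", "IIIB"], p=stage_p[g])
        gender = "male" if rng.random() < male_p[g] else "female"
        age = int(np.clip(round(rng.normal(age_mean[g], 11.0)), 25, 90))
        rows.append(
            {
                "sample_id": s,
                "group": g,
                "pair_id": None,
                "stage": stage,
                "gender": gender,
                "age": age,
            }
        )
    return pd.DataFrame(rows)


_SITE_WEIGHTS = {
    "liver": 0.40,
    "lung": 0.28,
    "bone": 0.14,
    "brain": 0.09,
    "skin_soft_tissue": 0.09,
}


def _sample_sites(rng) -> list[str]:
    n = int(rng.choice([1, 2, 3], p=[0.75, 0.20, 0.05]))
    sites = list(_SITE_WEIGHTS)
    w = np.array(list(_SITE_WEIGHTS.values()))
    return list(rng.choice(sites, size=n, replace=False, p=w / w.sum()))


def simulate_validation_cohort(
    cfg: SimulationConfig,
) -> tuple[CtMatrix, pd.DataFrame, SimulationTruth]:
    """Validation cohort Ct matrix plus clinical metadata.

    Group separation on each designated biomarker is calibrated on the dCt
    scale via the binormal identity so the expected empirical AUC equals the
    configured target. True biomarker positivity (the realized relative
    expression of the first configured biomarker against the first
    reference, split at the cohort median) drives the survival hazard:
    time ~ Exponential(h0 * HR^positive), right-censored at
    ``followup_months``; the event flag records progression before the
    censoring horizon.
    """
    rng = _rng(cfg, 2)
    n_met, n_non = cfg.n_validation_met, cfg.n_validation_non
    sample_ids = [f"M{i + 1:03d}" for i in range(n_met)] + [
        f"N{i + 1:03d}" for i in range(n_non)
    ]
    groups = [GROUP_METASTASIS] * n_met + [GROUP_NON_METASTASIS] * n_non
    plate_of_sample = {s: f"plate{(i % 3) + 1}" for i, s in enumerate(sample_ids)}

    mu: dict[str, float] = {}
    bio: dict[str, float] = {}
    for a in cfg.reference_assays:
        mu[a] = cfg.reference_assays[a][0]
        bio[a] = cfg.reference_bio_sd(a)
    for a, mean in cfg.failed_reference_assays.items():
        mu[a] = mean
        bio[a] = cfg.sigma_pair
    for a in cfg.validation_assays:
        if a not in mu:
            mu[a] = float(rng.uniform(28.0, 33.0))
            bio[a] = cfg.sigma_bio
    assays = list(mu)
    mu_v = np.array([mu[a] for a in assays])
    bio_v = np.array([bio[a] for a in assays])

    # binormal calibration of the metastasis shift per designated biomarker
    ref_bio_var = float(
        np.mean([cfg.reference_bio_sd(a) ** 2 for a in cfg.reference_assays])
    )
    is_met = np.array([g == GROUP_METASTASIS for g in groups])
    shifts = np.zeros((len(assays), len(sample_ids)))
    for a, auc in cfg.validation_auc.items():
        s = np.sqrt(bio[a] ** 2 + ref_bio_var + 2.0 * cfg.sigma_ct**2)
        delta = float(np.sqrt(2.0) * s * stats.norm.ppf(auc))
        shifts[assays.index(a), is_met] = -delta

    cell_bio = rng.normal(0.0, 1.0, (len(assays), len(sample_ids))) * bio_v[:, None]
    eps = rng.normal(0.0, cfg.sigma_ct, (len(assays), len(sample_ids)))
    ct = mu_v[:, None] + cell_bio + shifts + eps
    m = _finish_matrix(cfg, ct, assays, sample_ids, plate_of_sample, rng)

    table = _sample_clinical(cfg, sample_ids, groups, rng)

    # true positivity from the realized expression of the primary biomarker
    primary = next(iter(cfg.validation_auc), None) or cfg.validation_assays[0]
    ref = next(iter(cfg.reference_assays))
    score = -(m.ct.loc[primary] - m.ct.loc[ref])
    pos_true = (score > score.median()).to_dict()

    hazard = np.array(
        [
            cfg.baseline_hazard * (cfg.hazard_ratio if pos_true[s] else 1.0)
            for s in sample_ids
        ]
    )
    raw_times = rng.exponential(1.0 / hazard)
    event = raw_times < cfg.followup_months
    table["pfs_months"] = np.where(event, raw_times, cfg.followup_months).round(2)
    table["event"] = event
    table["met_sites"] = [
        _sample_sites(rng) if g == GROUP_METASTASIS else [] for g in groups
    ]

    truth = _make_truth(cfg)
    truth.positive_true = {k: bool(v) for k, v in pos_true.items()}
    return m, table, truth


def simulate_paired_tissue(cfg: SimulationConfig) -> pd.DataFrame:
    """Paired tumour/adjacent tissue expression for the assays in
    ``tissue_down_fraction``.

    Per pair, the tumour/adjacent log2 ratio is sign * |N(effect, 0.5)| with
    the sign negative (down-regulated in tumour) with the configured
    probability; a fraction of 0.5 therefore gives a sign-symmetric null on
    the log scale. Columns: pair_id, assay_id, tumour, adjacent (linear
    expression).
    """
    rng = _rng(cfg, 3)
    rows = []
    for assay, f_down in cfg.tissue_down_fraction.items():
        for i in range(cfg.tissue_n_pairs):
            sign = -1.0 if rng.random() < f_down else 1.0
            lr = sign * abs(rng.normal(cfg.tissue_effect_log2, 0.5))
            adjacent = float(2.0 ** rng.normal(5.0, 1.0))
            rows.append(
                {
                    "pair_id": f"T{i + 1:03d}",
                    "assay_id": assay,
                    "tumour": adjacent * 2.0**lr,
                    "adjacent": adjacent,
                }
            )
    return pd.DataFrame(rows)


def simulate_cell_medium(
    cfg: SimulationConfig, medium_shift_log2: float = 2.0
) -> pd.DataFrame:
    """Cell-line vs culture-medium log2 expression triplicates for the
    designated biomarkers (exosome-exported miRNAs sit higher in the medium
    by ``medium_shift_log2``)."""
    rng = _rng(cfg, 4)
    rows = []
    assays = list(cfg.validation_auc) or list(cfg.tissue_down_fraction)
    for line in ("AGS", "SNU1"):
        for assay in assays:
            base = rng.uniform(3.0, 6.0)
            for comp, shift in (("cells", 0.0), ("medium", medium_shift_log2)):
                for rep in range(1, cfg.n_replicates_cellline + 1):
                    rows.append(
                        {
                            "cell_line": line,
                            "assay_id": assay,
                            "compartment": comp,
                            "replicate": rep,
                            "log2_expression": base + shift + rng.normal(0.0, 0.3),
                        }
                    )
    return pd.DataFrame(rows)


def _write_layout(m: CtMatrix, path: Path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"plates": dict(m.plate_of_sample)}, fh, sort_keys=True)


def write_all_inputs(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``; returns the
    path of each artifact."""
    from .qpcr_io import write_ct_matrix, write_sample_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiling_ct": outdir / "ct_matrix.csv",
        "profiling_layout": outdir / "profiling_layout.yaml",
        "pairs": outdir / "pairs.csv",
        "validation_ct": outdir / "validation_ct.csv",
        "validation_layout": outdir / "validation_layout.yaml",
        "samples": outdir / "samples.csv",
        "tissue": outdir / "tissue_pairs.csv",
        "cell_medium": outdir / "cell_medium.csv",
        "truth": outdir / "truth.json",
    }
    prof, pairs, _ = simulate_profiling_pairs(cfg)
    write_ct_matrix(prof, paths["profiling_ct"])
    _write_layout(prof, paths["profiling_layout"])
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "case_sample": p.case_sample,
                "control_sample": p.control_sample,
            }
            for p in pairs
        ]
    ).to_csv(paths["pairs"], index=False)
    val, table, truth = simulate_validation_cohort(cfg)
    write_ct_matrix(val, paths["validation_ct"])
    _write_layout(val, paths["validation_layout"])
    write_sample_table(table, paths["samples"])
    simulate_paired_tissue(cfg).to_csv(paths["tissue"], index=False)
    simulate_cell_medium(cfg).to_csv(paths["cell_medium"], index=False)
    truth.to_json(paths["truth"])
    return paths
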