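"""Synthetic travelling-heads cohorts with known scanner effects.

The generator emulates the structure of a travelling-heads harmonisation
study: every subject is scanned once on every scanner, and a subset of
subjects additionally completes several within-scanner repeats on one
designated scanner each.  IDP values follow an additive-location /
multiplicative-scale batch model

    y[s, b, r, v] = alpha[v] + x[s] . beta[v] + u[s, v]
                    + gamma[b, v] + eta[b, s, v] + delta[b, v] * eps[s, b, r, v]

with subject (biological) effects ``u ~ N(0, tau^2)``, additive scanner
offsets ``gamma ~ N(0, sigma_gamma^2)``, multiplicative scanner noise scales
``delta`` drawn log-uniformly, and i.i.d. session noise ``eps ~ N(0,
sigma^2)``.  ``eta`` is an optional scanner-by-subject interaction whose
variance is partly shared between scanners of the same vendor; it is what
makes subject rankings agree better within a vendor than across vendors,
which a purely additive per-scanner offset cannot produce (a constant added
to every subject leaves the subject ordering untouched).

All dispersion parameters are expressed as fractions of each IDP's baseline
mean, so coefficient-of-variation statistics are comparable across IDPs
regardless of their (arbitrary) units.  The returned :class:`GroundTruth`
carries every drawn effect, enabling parameter-recovery tests of the
harmonisation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tables import CategoryMap, ContractError, SessionRecord, StudyData

__all__ = [
    "DesignSpec",
    "SimulationConfig",
    "GroundTruth",
    "build_design",
    "simulate_idps",
    "simulate_iqms",
    "simulate_study",
    "preset_travelling_heads",
]


@dataclass(frozen=True)
class DesignSpec:
    """A travelling-heads acquisition design.

    Every subject is scanned once (repeat_index 0) on every scanner;
    ``repeat_plan`` grants selected subjects extra within-scanner repeats on
    one designated scanner each.
    """

    subject_ids: Tuple[str, ...]
    scanner_ids: Tuple[str, ...]
    repeat_plan: Mapping[str, Tuple[str, int]]  # subject -> (scanner, n_extra)
    vendor_of: Mapping[str, str]
    site_of: Mapping[str, str]
    ages: Optional[Mapping[str, float]] = None
    sexes: Optional[Mapping[str, str]] = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_scanners(self) -> int:
        return len(self.scanner_ids)

    def default_ages(self) -> dict[str, float]:
        # evenly spaced across the adult range 24-48 years
        grid = np.linspace(24.0, 48.0, self.n_subjects)
        return {s: float(a) for s, a in zip(self.subject_ids, grid)}

    def default_sexes(self) -> dict[str, str]:
        # 8:2 male-to-female ratio, deterministic assignment
        n_f = max(1, round(0.2 * self.n_subjects)) if self.n_subjects > 1 else 0
        return {
            s: ("F" if i >= self.n_subjects - n_f else "M")
            for i, s in enumerate(self.subject_ids)
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; dispersions are fractions of each IDP's baseline.

    ``biological_sd``, ``scanner_additive_sd``, ``noise_sd`` and
    ``interaction_sd`` multiply the IDP's baseline mean ``alpha_v``, so with
    the defaults every IDP has ~5% biological, ~4% additive-scanner, ~1%
    within-scanner-noise and ~0.5% scanner-by-subject dispersion relative to
    its mean.  ``vendor_share`` is the fraction of the interaction variance
    shared among scanners of the same vendor.
    """

    n_idps_per_category: Mapping[str, int]
    category_modality: Mapping[str, str] = field(default_factory=dict)
    alpha_mean: float = 100.0
    alpha_spread: float = 0.3  # alpha_v ~ alpha_mean * U(1-spread, 1+spread)
    beta_age_sd: float = 0.002  # per-year covariate slope, fraction of alpha_v
    beta_sex_sd: float = 0.02  # male/female offset, fraction of alpha_v
    biological_sd: float = 0.05  # tau_v / alpha_v
    scanner_additive_sd: float = 0.04  # sd of gamma_bv / alpha_v
    scanner_scale_range: Tuple[float, float] = (0.8, 1.25)  # delta_bv, log-uniform
    noise_sd: float = 0.01  # sigma_v / alpha_v
    interaction_sd: float = 0.005  # sd of eta_bsv / alpha_v
    vendor_share: float = 0.5  # vendor-shared fraction of interaction variance
    iqm_names: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: {
            "T1w": ("t1w_snr", "t1w_cnr"),
            "dMRI": ("dmri_snr", "dmri_outlier_rate"),
            "rfMRI": ("rfmri_tsnr", "rfmri_fd"),
        }
    )
    iqm_scanner_sd: float = 1.0
    iqm_subject_sd: float = 1.0
    iqm_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scanner_scale_range
        if not (0 < lo <= hi):
            raise ContractError("scanner_scale_range must lie in (0, inf)")
        for name in (
            "alpha_spread",
            "beta_age_sd",
            "beta_sex_sd",
            "biological_sd",
            "scanner_additive_sd",
            "noise_sd",
            "interaction_sd",
        ):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        if not 0 <= self.vendor_share <= 1:
            raise ContractError("vendor_share must lie in [0, 1]")

    @property
    def idp_names(self) -> list[str]:
        names: list[str] = []
        for cat in sorted(self.n_idps_per_category):
            n = self.n_idps_per_category[cat]
            names.extend(f"{cat}_{i:03d}" for i in range(1, n + 1))
        return names

    def category_map(self) -> CategoryMap:
        rows = []
        for cat in sorted(self.n_idps_per_category):
            modality = self.category_modality.get(cat, "synthetic")
            for i in range(1, self.n_idps_per_category[cat] + 1):
                rows.append((f"{cat}_{i:03d}", cat, cat, modality))
        df = pd.DataFrame(
            rows, columns=["idp_name", "category", "group", "modality"]
        ).set_index("idp_name")
        return CategoryMap(entries=df)


@dataclass
class GroundTruth:
    """Every effect drawn by the generator, for parameter-recovery tests."""

    alpha: pd.Series  # per IDP baseline mean
    beta: pd.DataFrame  # IDP x (age, sex) covariate effects
    tau: pd.Series  # per IDP biological sd
    sigma: pd.Series  # per IDP within-scanner noise sd
    gamma: pd.DataFrame  # scanner x IDP additive effects
    delta: pd.DataFrame  # scanner x IDP multiplicative noise scales
    subject_effects: pd.DataFrame  # subject x IDP biological deviations
    interaction: pd.DataFrame  # (scanner, subject) MultiIndex x IDP


# fixed spawn order of the named substreams hanging off the global seed
_STREAMS = (
    "alpha",
    "beta",
    "gamma_vendor",
    "gamma_scanner",
    "delta",
    "subject",
    "interaction_vendor",
    "interaction_scanner",
    "noise",
    "iqm",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def build_design(spec: DesignSpec) -> list[SessionRecord]:
    """Deterministically enumerate the sessions of a design.

    Session ids follow ``<subject>_<scanner>_rep<k>``; each subject gets a
    repeat_index-0 session on every scanner, plus ``n_extra`` further repeats
    on the scanner designated in ``repeat_plan``.
    """
    known_subjects = set(spec.subject_ids)
    known_scanners = set(spec.scanner_ids)
    for sub, (scan, n_extra) in spec.repeat_plan.items():
        if sub not in known_subjects:
            raise ContractError(f"repeat_plan references unknown subject {sub!r}")
        if scan not in known_scanners:
            raise ContractError(f"repeat_plan references unknown scanner {scan!r}")
        if n_extra < 0:
            raise ContractError("n_extra_repeats must be >= 0")
    missing_vendor = known_scanners - set(spec.vendor_of)
    if missing_vendor:
        raise ContractError(f"vendor_of missing scanner(s): {sorted(missing_vendor)}")

    ages = dict(spec.ages) if spec.ages is not None else spec.default_ages()
    sexes = dict(spec.sexes) if spec.sexes is not None else spec.default_sexes()

    records: list[SessionRecord] = []
    for sub in spec.subject_ids:
        for scan in spec.scanner_ids:
            n_rep = 0
            if sub in spec.repeat_plan and spec.repeat_plan[sub][0] == scan:
                n_rep = spec.repeat_plan[sub][1]
            for k in range(n_rep + 1):
                records.append(
                    SessionRecord(
                        session_id=f"{sub}_{scan}_rep{k}",
                        subject_id=sub,
                        scanner_id=scan,
                        site=spec.site_of.get(scan, "site-unknown"),
                        vendor=spec.vendor_of[scan],
                        repeat_index=k,
                        age=ages[sub],
                        sex=sexes[sub],
                    )
                )
    return records


def _sessions_frame(design: Sequence[SessionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in design])


def simulate_idps(
    design: Sequence[SessionRecord], config: SimulationConfig
) -> tuple[StudyData, GroundTruth]:
    """Draw an IDP table for ``design`` under the location/scale batch model.

    Identical (design, config) pairs produce bit-identical tables: one global
    seed feeds a named substream per random quantity, so e.g. the subject
    effects do not change when the number of IQMs does.
    """
    rngs = _rngs(config.seed)
    sessions = _sessions_frame(design)
    idp_names = config.idp_names
    n_idp = len(idp_names)
    if n_idp == 0:
        raise ContractError("config defines no IDPs")

    subjects = list(dict.fromkeys(sessions["subject_id"]))
    scanners = list(dict.fromkeys(sessions["scanner_id"]))
    vendors = list(dict.fromkeys(sessions["vendor"]))
    vendor_of = dict(zip(sessions["scanner_id"], sessions["vendor"]))

    alpha = config.alpha_mean * (
        1 + config.alpha_spread * (2 * rngs["alpha"].random(n_idp) - 1)
    )
    beta = np.column_stack(
        [
            rngs["beta"].normal(0.0, config.beta_age_sd, n_idp) * alpha,
            rngs["beta"].normal(0.0, config.beta_sex_sd, n_idp) * alpha,
        ]
    )
    tau = config.biological_sd * alpha
    sigma = config.noise_sd * alpha

    # additive scanner offsets, vendor-clustered via a variance share
    w = config.vendor_share
    g_vendor = rngs["gamma_vendor"].normal(size=(len(vendors), n_idp))
    g_scanner = rngs["gamma_scanner"].normal(size=(len(scanners), n_idp))
    v_idx = {v: i for i, v in enumerate(vendors)}
    gamma = np.empty((len(scanners), n_idp))
    for bi, b in enumerate(scanners):
        mix = np.sqrt(w) * g_vendor[v_idx[vendor_of[b]]] + np.sqrt(1 - w) * g_scanner[bi]
        gamma[bi] = config.scanner_additive_sd * alpha * mix

    lo, hi = config.scanner_scale_range
    if hi == lo:
        delta = np.full((len(scanners), n_idp), lo)
    else:
        delta = np.exp(
            rngs["delta"].uniform(np.log(lo), np.log(hi), size=(len(scanners), n_idp))
        )

    u = rngs["subject"].normal(size=(len(subjects), n_idp)) * tau

    e_vendor = rngs["interaction_vendor"].normal(
        size=(len(vendors), len(subjects), n_idp)
    )
    e_scanner = rngs["interaction_scanner"].normal(
        size=(len(scanners), len(subjects), n_idp)
    )
    eta = np.empty((len(scanners), len(subjects), n_idp))
    for bi, b in enumerate(scanners):
        eta[bi] = config.interaction_sd * alpha * (
            np.sqrt(w) * e_vendor[v_idx[vendor_of[b]]] + np.sqrt(1 - w) * e_scanner[bi]
        )

    s_idx = {s: i for i, s in enumerate(subjects)}
    b_idx = {b: i for i, b in enumerate(scanners)}
    age = sessions["age"].to_numpy(float)
    age_c = age - age.mean()
    sex01 = (sessions["sex"].to_numpy() == sorted(set(sessions["sex"]))[-1]).astype(
        float
    )
    rows = np.empty((len(sessions), n_idp))
    eps = rngs["noise"].normal(size=(len(sessions), n_idp)) * sigma
    for i, row in enumerate(sessions.itertuples(index=False)):
        si, bi = s_idx[row.subject_id], b_idx[row.scanner_id]
        rows[i] = (
            alpha
            + age_c[i] * beta[:, 0]
            + sex01[i] * beta[:, 1]
            + u[si]
            + gamma[bi]
            + eta[bi, si]
            + delta[bi] * eps[i]
        )

    idps = pd.DataFrame(rows, index=sessions["session_id"].tolist(), columns=idp_names)
    idps.index.name = "session_id"
    study = StudyData(
        sessions=sessions, idps=idps, categories=config.category_map(), iqms=None
    )
    study.validate()

    inter_index = pd.MultiIndex.from_product(
        [scanners, subjects], names=["scanner_id", "subject_id"]
    )
    truth = GroundTruth(
        alpha=pd.Series(alpha, index=idp_names, name="alpha"),
        beta=pd.DataFrame(beta, index=idp_names, columns=["age", "sex"]),
        tau=pd.Series(tau, index=idp_names, name="tau"),
        sigma=pd.Series(sigma, index=idp_names, name="sigma"),
        gamma=pd.DataFrame(gamma, index=scanners, columns=idp_names),
        delta=pd.DataFrame(delta, index=scanners, columns=idp_names),
        subject_effects=pd.DataFrame(u, index=subjects, columns=idp_names),
        interaction=pd.DataFrame(
            eta.reshape(len(scanners) * len(subjects), n_idp),
            index=inter_index,
            columns=idp_names,
        ),
    )
    return study, truth


def simulate_iqms(
    design: Sequence[SessionRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Draw a per-session IQM table with scanner and subject offsets plus noise.

    A stand-in for automated quality-control outputs: each metric is the sum
    of a scanner-level offset, a subject-level offset and session noise, so
    downstream z-score heatmaps have known structure.
    """
    rngs = _rngs(config.seed)
    rng = rngs["iqm"]
    sessions = _sessions_frame(design)
    subjects = list(dict.fromkeys(sessions["subject_id"]))
    scanners = list(dict.fromkeys(sessions["scanner_id"]))
    names = [n for mod in sorted(config.iqm_names) for n in config.iqm_names[mod]]
    n_iqm = len(names)

    scan_off = rng.normal(0.0, config.iqm_scanner_sd, size=(len(scanners), n_iqm))
    subj_off = rng.normal(0.0, config.iqm_subject_sd, size=(len(subjects), n_iqm))
    noise = rng.normal(0.0, config.iqm_noise_sd, size=(len(sessions), n_iqm))

    s_idx = {s: i for i, s in enumerate(subjects)}
    b_idx = {b: i for i, b in enumerate(scanners)}
    rows = np.empty((len(sessions), n_iqm))
    for i, row in enumerate(sessions.itertuples(index=False)):
        rows[i] = scan_off[b_idx[row.scanner_id]] + subj_off[s_idx[row.subject_id]] + noise[i]
    iqms = pd.DataFrame(rows, index=sessions["session_id"].tolist(), columns=names)
    iqms.index.name = "session_id"
    return iqms


def simulate_study(
    spec: DesignSpec, config: SimulationConfig, with_iqms: bool = True
) -> tuple[StudyData, GroundTruth]:
    """Build the design and simulate IDPs (and IQMs) in one call."""
    design = build_design(spec)
    study, truth = simulate_idps(design, config)
    if with_iqms:
        study.iqms = simulate_iqms(design, config)
        study.validate()
    return study, truth


def preset_travelling_heads(seed: int = 0) -> tuple[DesignSpec, SimulationConfig]:
    """The benchmark's reference design and generative configuration.

    10 subjects x 6 scanners from 3 vendors at 5 sites; 4 subjects complete
    5 extra within-scanner repeats each on a designated scanner, giving
    60 primary + 20 repeat = 80 sessions.  360 IDPs span 8 categories,
    including a 210-edge connectivity category (the upper triangle of a
    21-node network) subject to top-fraction edge selection downstream.
    """
    subjects = tuple(f"sub-{i:02d}" for i in range(1, 11))
    scanners = (
        "GE-MR750",
        "Philips-Achieva",
        "Philips-Ingenia",
        "Siemens-Prisma32",
        "Siemens-Prisma64",
        "Siemens-Trio",
    )
    vendor_of = {
        "GE-MR750": "GE",
        "Philips-Achieva": "Philips",
        "Philips-Ingenia": "Philips",
        "Siemens-Prisma32": "Siemens",
        "Siemens-Prisma64": "Siemens",
        "Siemens-Trio": "Siemens",
    }
    # six scanners across five sites: the two Prismas share a site
    site_of = {
        "GE-MR750": "site-1",
        "Philips-Achieva": "site-2",
        "Philips-Ingenia": "site-3",
        "Siemens-Prisma32": "site-4",
        "Siemens-Prisma64": "site-4",
        "Siemens-Trio": "site-5",
    }
    repeat_plan = {
        "sub-01": ("Philips-Achieva", 5),
        "sub-02": ("Siemens-Prisma32", 5),
        "sub-03": ("Siemens-Trio", 5),
        "sub-04": ("Siemens-Prisma64", 5),
    }
    spec = DesignSpec(
        subject_ids=subjects,
        scanner_ids=scanners,
        repeat_plan=repeat_plan,
        vendor_of=vendor_of,
        site_of=site_of,
    )
    config = SimulationConfig(
        n_idps_per_category={
            "subcortical_volume": 14,
            "tissue_volume": 10,
            "subcortical_t2star": 14,
            "cortical_volume": 37,
            "dmri_fa": 27,
            "dmri_md": 27,
            "fc_amplitude": 21,
            "fc_edge": 210,
        },
        category_modality={
            "subcortical_volume": "T1w",
            "tissue_volume": "T1w",
            "cortical_volume": "T1w",
            "subcortical_t2star": "SWI",
            "dmri_fa": "dMRI",
            "dmri_md": "dMRI",
            "fc_amplitude": "rfMRI",
            "fc_edge": "rfMRI",
        },
        seed=seed,
    )
    return spec, config
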