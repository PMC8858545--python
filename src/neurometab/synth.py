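"""Synthetic two-genotype MRS/behavior cohorts with known ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes, via a single latent *sociability* score per animal:

    s_i ~ Normal(mu_genotype, 1)

The social-preference index is an affine function of s plus noise (mapped
to exploration times so the PI algebra round-trips exactly), and each
metabolite concentration is

    baseline + genotype_effect * 1[KO] + coupling * s + Normal(0, sd)

so a single mechanism yields both the genotype group difference and the
behavior-metabolite correlation.  Ratios (e.g. Glu/GABA) are never
generated directly: the generator shifts the *component* metabolites and
the pipeline must derive the ratios itself.  CRLB %SD values are drawn per
metabolite from a shifted gamma with a configurable tail above the 50%
filter threshold so the quality-control path is exercised.

All randomness flows from one integer seed; identical (spec, seed) runs
produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import METABOLITES, REGIONS

__all__ = ["CohortSpec", "exploration_times_from_pi", "generate_cohort", "write_cohort"]

#: baseline concentration means (arbitrary units, stylized rodent-brain values)
_DEFAULT_MEANS = {
    "Ala": 0.8, "Asp": 2.5, "Cr": 4.0, "PCr": 4.0, "GABA": 2.0, "Glc": 2.0,
    "Gln": 3.0, "Glu": 9.0, "GSH": 1.5, "GPC": 0.8, "Lac": 2.0, "Ins": 5.0,
    "NAA": 8.0, "NAAG": 0.6, "PCh": 0.6, "Scyllo": 0.3, "Tau": 8.0,
}
#: baseline within-group SDs (roughly 8-15% of the mean)
_DEFAULT_SDS = {
    "Ala": 0.15, "Asp": 0.35, "Cr": 0.45, "PCr": 0.45, "GABA": 0.30, "Glc": 0.35,
    "Gln": 0.40, "Glu": 0.90, "GSH": 0.20, "GPC": 0.12, "Lac": 0.35, "Ins": 0.55,
    "NAA": 0.80, "NAAG": 0.10, "PCh": 0.10, "Scyllo": 0.06, "Tau": 0.85,
}
#: low-SNR metabolites whose CRLB distribution has a tail beyond 50%, and
#: very-low-SNR ones that usually fail the inclusion rule (as the weakest
#: resonances do in practice)
_HARD_METS = {"Ala", "NAAG", "GPC", "PCh", "Cr"}
_VHARD_METS = {"Glc", "Lac", "Scyllo"}
#: shifted-gamma CRLB parameters (loc %, shape, scale %)
_CRLB_EASY = (2.0, 2.0, 3.0)
_CRLB_HARD = (5.0, 1.8, 14.0)
_CRLB_VHARD = (12.0, 2.0, 30.0)

#: KO mean shifts (units) reproducing the study's directions: lower
#: prefrontal Glu/GABA and tCr (hence higher NAA/tCr), higher hippocampal Glx
_DEFAULT_GENOTYPE_EFFECTS = {
    ("PFC", "Glu"): -0.52,
    ("PFC", "GABA"): +0.26,
    ("PFC", "Cr"): -0.45,
    ("PFC", "PCr"): -0.45,
    ("HPC", "Glu"): +0.55,
    ("HPC", "Gln"): +0.35,
}
#: latent-sociability couplings (units per latent SD) on prefrontal
#: components so Glu/GABA and tCr correlate positively with preference
_DEFAULT_COUPLING = {
    ("PFC", "Glu"): +0.50,
    ("PFC", "GABA"): -0.15,
    ("PFC", "Cr"): +0.22,
    ("PFC", "PCr"): +0.22,
}


def _normalize_keymap(d: dict, what: str) -> dict:
    out = {}
    for k, v in d.items():
        if not (isinstance(k, tuple) and len(k) == 2):
            raise ValueError(f"{what} keys must be (region, metabolite) tuples")
        region, met = k
        if region not in REGIONS:
            raise ValueError(f"{what}: unknown region {region!r}")
        if met not in METABOLITES:
            raise ValueError(
                f"{what}: {met!r} is not a raw metabolite; ratios/sums must be "
                "induced by shifting their components"
            )
        out[(region, met)] = float(v)
    return out


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults encode the study conditions: 9 wild-type vs 11 knockout
    animals, 17 metabolites in two regions, KO effects on prefrontal
    Glu/GABA components and total creatine and on hippocampal Glx
    components, and a latent sociability score coupling the
    social-preference index to prefrontal metabolite levels.
    """

    n_wt: int = 9
    n_ko: int = 11
    seed: int = 0
    latent_mean_wt: float = 1.0
    latent_mean_ko: float = 0.0
    latent_coupling: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    genotype_effects: dict = field(default_factory=lambda: dict(_DEFAULT_GENOTYPE_EFFECTS))
    baseline_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    baseline_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    crlb_model: dict = field(
        default_factory=lambda: {
            m: (
                _CRLB_VHARD if m in _VHARD_METS
                else _CRLB_HARD if m in _HARD_METS
                else _CRLB_EASY
            )
            for m in METABOLITES
        }
    )
    behavior_noise_sd: float = 0.15
    pi_latent_slope: float = 0.45
    pi_latent_slope_recognition: float = 0.0
    session_total_s: float = 600.0
    regions: tuple = REGIONS

    def validate(self) -> "CohortSpec":
        if self.n_wt < 2 or self.n_ko < 2:
            raise ValueError("need at least 2 animals per genotype")
        if any(sd <= 0 for sd in self.baseline_sds.values()):
            raise ValueError("all baseline SDs must be positive")
        unknown = set(self.baseline_means) - set(METABOLITES)
        if unknown:
            raise ValueError(f"baseline means for unknown metabolites: {sorted(unknown)}")
        for m, (loc, shape, scale) in self.crlb_model.items():
            if m not in METABOLITES:
                raise ValueError(f"crlb_model for unknown metabolite {m!r}")
            if scale < 0 or shape <= 0 or loc < 0:
                raise ValueError(f"invalid CRLB parameters for {m}")
        if self.behavior_noise_sd < 0:
            raise ValueError("behavior_noise_sd must be non-negative")
        self.latent_coupling = _normalize_keymap(self.latent_coupling, "latent_coupling")
        self.genotype_effects = _normalize_keymap(self.genotype_effects, "genotype_effects")
        return self


def exploration_times_from_pi(pi: float, total_time: float) -> tuple[float, float]:
    """Invert the preference index into a (target, other) time split.

    Guarantees ``et_target + et_other == total_time`` and
    ``(et_target - et_other)/(et_target + et_other) == pi`` exactly.
    """
    if not -1.0 <= pi <= 1.0:
        raise ValueError(f"preference index {pi} outside [-1, 1]")
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    et_target = total_time * (1.0 + pi) / 2.0
    return et_target, total_time - et_target


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic cohort.

    Returns
    -------
    animals : DataFrame
        Long behavior table: id, genotype, session (preference /
        recognition), et_target, et_other, plus the (unclipped) generative
        pi and latent score for reference.
    measurements : DataFrame
        Long MRS table: id, region, metabolite, concentration, crlb_pct.
    truth : dict
        All generative parameters, per-animal latent scores, and the
        per-(region, metabolite) group means implied by the spec.
    """
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_wt + spec.n_ko
    ids = [f"M{i + 1:03d}" for i in range(n)]
    genotypes = np.array(["WT"] * spec.n_wt + ["KO"] * spec.n_ko)
    latent_mu = np.where(genotypes == "WT", spec.latent_mean_wt, spec.latent_mean_ko)
    s = latent_mu + rng.normal(0.0, 1.0, size=n)

    animal_rows = []
    for session, slope in [
        ("preference", spec.pi_latent_slope),
        ("recognition", spec.pi_latent_slope_recognition),
    ]:
        pi_raw = slope * s + rng.normal(0.0, spec.behavior_noise_sd, size=n)
        pi = np.clip(pi_raw, -1.0, 1.0)
        for i in range(n):
            et_t, et_o = exploration_times_from_pi(pi[i], spec.session_total_s)
            animal_rows.append(
                {
                    "id": ids[i], "genotype": genotypes[i], "session": session,
                    "et_target": et_t, "et_other": et_o,
                    "pi_generative": pi_raw[i], "latent_s": s[i],
                }
            )
    animals = pd.DataFrame(animal_rows)

    mets = [m for m in METABOLITES if m in spec.baseline_means]
    meas_rows = []
    for region in spec.regions:
        for met in mets:
            mu = spec.baseline_means[met]
            sd = spec.baseline_sds[met]
            eff = spec.genotype_effects.get((region, met), 0.0)
            coup = spec.latent_coupling.get((region, met), 0.0)
            conc = (
                mu
                + eff * (genotypes == "KO")
                + coup * s
                + rng.normal(0.0, sd, size=n)
            )
            conc = np.maximum(conc, 0.0)  # concentrations are physical
            loc, shape, scale = spec.crlb_model[met]
            crlb = np.full(n, float(loc))
            if scale > 0:
                crlb += rng.gamma(shape, scale, size=n)
            for i in range(n):
                meas_rows.append(
                    {
                        "id": ids[i], "region": region, "metabolite": met,
                        "concentration": conc[i], "crlb_pct": float(crlb[i]),
                    }
                )
    measurements = pd.DataFrame(meas_rows)

    truth = {
        "seed": spec.seed,
        "n_wt": spec.n_wt,
        "n_ko": spec.n_ko,
        "latent_mean_wt": spec.latent_mean_wt,
        "latent_mean_ko": spec.latent_mean_ko,
        "latent_coupling": {f"{r}:{m}": v for (r, m), v in spec.latent_coupling.items()},
        "genotype_effects": {f"{r}:{m}": v for (r, m), v in spec.genotype_effects.items()},
        "baseline_means": dict(spec.baseline_means),
        "baseline_sds": dict(spec.baseline_sds),
        "behavior_noise_sd": spec.behavior_noise_sd,
        "pi_latent_slope": spec.pi_latent_slope,
        "latent_scores": dict(zip(ids, s.tolist())),
    }
    return animals, measurements, truth


def generative_feature_samples(
    spec: CohortSpec,
    region: str,
    feature: str,
    genotype: str,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo draws of one derived or raw feature from the generative model.

    Used to evaluate the ground-truth distribution (and hence AUC) implied
    by a spec — a ratio of correlated normals has no simple closed form, so
    truth-level quantities are computed by large-n sampling.
    """
    from .features import DERIVED_FEATURES

    is_ko = genotype == "KO"
    s = (spec.latent_mean_ko if is_ko else spec.latent_mean_wt) + rng.normal(0, 1, n_draws)

    def raw(met: str) -> np.ndarray:
        mu = spec.baseline_means[met]
        sd = spec.baseline_sds[met]
        eff = spec.genotype_effects.get((region, met), 0.0) if is_ko else 0.0
        coup = spec.latent_coupling.get((region, met), 0.0)
        return np.maximum(mu + eff + coup * s + rng.normal(0, sd, n_draws), 0.0)

    def value(name: str) -> np.ndarray:
        if name in DERIVED_FEATURES:
            kind, (a, b) = DERIVED_FEATURES[name]
            va, vb = value(a), value(b)
            return va + vb if kind == "sum" else va / vb
        return raw(name)

    return value(feature)


def write_cohort(animals, measurements, truth, outdir) -> None:
    """Write animals.csv, metabolites.csv and truth.json to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    animals.to_csv(out / "animals.csv", index=False, float_format="%.10g")
    measurements.to_csv(out / "metabolites.csv", index=False, float_format="%.10g")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
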