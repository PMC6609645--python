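"""Synthetic multi-tissue metabolomics cohorts.

Generates datasets with the statistical structure the analysis assumes: a
43-donor cohort (17 normoglycemic / 13 pre-diabetes / 13 T2D by default, with
covariates drawn from the published cohort's group means and SDs), five
tissues (VAT, liver, pancreatic islets, skeletal muscle, serum), two disjoint
platforms (142 GC-MS + 144 LC-MS metabolites), log-normal baseline
intensities, optional within-tissue correlation blocks, configurable
class x tissue group effects on the standardized log2 scale, and
intensity-dependent (left-censored) missingness.

Every generated quantity is deterministic given the seed, and the planted
ground truth (group shifts actually realized, module memberships) travels
with the dataset so downstream recovery can be scored.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MetmapError
from .ingest_annotate import (
    COMPARISONS,
    IntensityTable,
    MetaboliteRecord,
    PHENOTYPES,
    SampleRecord,
    TISSUES,
    PLATFORMS,
    mmolmol_to_percent,
    percent_to_mmolmol,
)

# HbA1c group bands on the IFCC mmol/mol scale (derived from the 5.7/6.5 %
# clinical cutoffs via the NGSP/IFCC master equation).
_H_LOW = percent_to_mmolmol(5.7)
_H_HIGH = percent_to_mmolmol(6.5)

#: Cohort covariate (mean, sd) per group: age in years, BMI in kg/m2,
#: HbA1c in mmol/mol, GSIS in mmol/L glucose-stimulated insulin secretion.
#: Sample weight (mg of frozen tissue) is a repository choice; the cohort
#: table does not report it.
DEFAULT_COVARIATE_DISTS: dict[str, dict[str, tuple[float, float]]] = {
    "age_years": {"control": (59, 10), "prediabetes": (64, 8), "T2D": (65, 7)},
    "bmi": {"control": (26.5, 3.8), "prediabetes": (27.6, 5.6), "T2D": (27.9, 5.6)},
    "hba1c_mmolmol": {"control": (36.2, 1.9), "prediabetes": (40.8, 1.8),
                      "T2D": (56.5, 15.5)},
    "gsis": {"control": (11.8, 5.6), "prediabetes": (15.1, 30.8), "T2D": (5.0, 2.5)},
    "sample_weight": {"control": (100.0, 15.0), "prediabetes": (100.0, 15.0),
                      "T2D": (100.0, 15.0)},
}

DEFAULT_GENDER_FRACTION_FEMALE = {
    "control": 7 / 17, "prediabetes": 4 / 13, "T2D": 4 / 13,
}

DEFAULT_CLASS_PROPORTIONS = {
    "lipids and lipid-like molecules": 0.45,
    "amino acids, peptides and analogues": 0.25,
    "carbohydrates and conjugates": 0.12,
    "nucleosides, nucleotides and analogues": 0.08,
    "bile acids and derivatives": 0.05,
    "organic acids and derivatives": 0.05,
}

_LIPID_SUBCLASSES = (("LPC", 0.30), ("carnitine", 0.30), ("NEFA", 0.20),
                     ("other_lipid", 0.20))
_AA_SUBCLASSES = (("BCAA", 0.20), ("AAA", 0.20), ("other_AA", 0.60))

_ROLES_BY_CLASS = {
    "lipids and lipid-like molecules": ("energy production", "membrane component",
                                        "fatty acid transport"),
    "amino acids, peptides and analogues": ("essential amino acid",
                                            "protein synthesis"),
    "carbohydrates and conjugates": ("energy source", "osmolyte"),
    "nucleosides, nucleotides and analogues": ("nucleic acid component",
                                               "signaling"),
    "bile acids and derivatives": ("lipid absorption", "cholesterol catabolism"),
    "organic acids and derivatives": ("energy production", "signaling"),
}

_N_PATHWAYS_PER_CLASS = 4


@dataclass
class CohortSpec:
    """Study-design parameters for cohort generation."""

    n_control: int = 17
    n_prediabetes: int = 13
    n_t2d: int = 13
    covariate_dists: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_DISTS)
    gender_fraction_female: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_GENDER_FRACTION_FEMALE)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_prediabetes", "n_t2d"):
            n = getattr(self, name)
            if not isinstance(n, int) or n < 2:
                raise ConfigurationError(f"{name} must be an integer >= 2, got {n!r}")
        for cov, per_group in self.covariate_dists.items():
            for group, (mean, sd) in per_group.items():
                if group not in PHENOTYPES:
                    raise ConfigurationError(f"unknown group {group!r} for {cov}")
                if sd < 0:
                    raise ConfigurationError(f"{cov}/{group}: sd must be >= 0")
        for group, frac in self.gender_fraction_female.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(
                    f"gender_fraction_female[{group}] must be in [0,1]")


@dataclass(frozen=True)
class EffectEntry:
    """One planted group shift: a metabolite class (curated class or
    sub-class label), a tissue, a comparison and a signed shift in
    within-group SD units on the log2 scale."""

    metabolite_class: str
    tissue: str
    comparison: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ConfigurationError(f"unknown tissue {self.tissue!r}")
        if self.comparison not in COMPARISONS:
            raise ConfigurationError(f"unknown comparison {self.comparison!r}")


@dataclass
class EffectSpec:
    entries: list[EffectEntry] = field(default_factory=list)

    @classmethod
    def from_tuples(cls, entries: Sequence[tuple[str, str, str, float]]) -> "EffectSpec":
        return cls([EffectEntry(*e) for e in entries])

    def shifted_groups(self, entry: EffectEntry) -> tuple[str, ...]:
        """Groups whose mean is shifted by ``effect_size`` for this entry.

        - T2D_vs_nonDM, T2D_vs_PD: shift T2D only.
        - PD_vs_CTRL: shift pre-diabetes *and* T2D (the early-marker pattern:
          the change appears at pre-diabetes and persists in overt disease).
        """
        if entry.comparison == "PD_vs_CTRL":
            return ("prediabetes", "T2D")
        return ("T2D",)


@dataclass
class MissingnessSpec:
    """Intensity-dependent missingness.  ``left_censor_weight`` = 0 gives
    MCAR; 1 concentrates missingness at the lowest intensities."""

    overall_rate: float = 0.15
    left_censor_weight: float = 0.8

    def validate(self) -> None:
        if not 0 <= self.overall_rate < 1:
            raise ConfigurationError("overall_rate must be in [0, 1)")
        if not 0 <= self.left_censor_weight <= 1:
            raise ConfigurationError("left_censor_weight must be in [0, 1]")
        if self.overall_rate >= 0.5:
            raise ConfigurationError(
                "overall_rate >= 0.5 would defeat the 25% missingness filter")


@dataclass(frozen=True)
class CorrBlock:
    """A planted intra-tissue correlation block (a 'functional module')."""

    tissue: str
    n_members: int = 6
    rho: float = 0.6
    sub_class: str | None = None
    shift: float = 0.0            # group-shift of the shared factor, SD units
    comparison: str = "T2D_vs_nonDM"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ConfigurationError(f"unknown tissue {self.tissue!r}")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must be in [0, 1)")
        if self.n_members < 2:
            raise ConfigurationError("n_members must be >= 2")


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth.

    ``complete_log2`` holds the pre-missingness log2 matrices (metabolites x
    samples) so planted effects can be recovered without the censoring step.
    """

    intensity_tables: dict[tuple[str, str], IntensityTable]
    samples: list[SampleRecord]
    annotations: list[MetaboliteRecord]
    truth: dict
    complete_log2: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      low: float = -np.inf, high: float = np.inf) -> np.ndarray:
    """Draw from N(mean, sd) clipped into (low, high) by redrawing (clip as
    last resort for extreme bands)."""
    x = rng.normal(mean, sd, size=n)
    for _ in range(50):
        bad = (x < low) | (x > high)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, low, high)


def generate_cohort(spec: CohortSpec | None = None) -> list[SampleRecord]:
    """Generate donor records for the three phenotype groups.

    HbA1c is drawn on the mmol/mol scale from the per-group distribution and
    constrained into the group's defining band; the % value is derived with
    the NGSP/IFCC master equation.  T2D subjects carry the medical-record
    flag (they are identified from records, not from HbA1c alone).
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bands = {
        "control": (10.0, _H_LOW - 1e-6),
        "prediabetes": (_H_LOW, _H_HIGH),
        "T2D": (_H_HIGH + 1e-6, 160.0),
    }
    counts = {"control": spec.n_control, "prediabetes": spec.n_prediabetes,
              "T2D": spec.n_t2d}
    records: list[SampleRecord] = []
    i = 0
    for group in PHENOTYPES:
        n = counts[group]
        dists = {c: spec.covariate_dists[c][group] for c in spec.covariate_dists}
        low, high = bands[group]
        h_mmol = _truncated_normal(rng, *dists["hba1c_mmolmol"], n, low, high)
        age = _truncated_normal(rng, *dists["age_years"], n, 18, 95)
        bmi = _truncated_normal(rng, *dists["bmi"], n, 15, 60)
        gsis = _truncated_normal(rng, *dists["gsis"], n, 0.1, np.inf)
        weight = _truncated_normal(rng, *dists["sample_weight"], n, 1.0, np.inf)
        female = rng.random(n) < spec.gender_fraction_female[group]
        for j in range(n):
            i += 1
            records.append(SampleRecord(
                sample_id=f"S{i:03d}",
                phenotype=group,
                hba1c_percent=float(mmolmol_to_percent(h_mmol[j])),
                hba1c_mmolmol=float(h_mmol[j]),
                gsis=float(gsis[j]),
                age_years=float(age[j]),
                bmi=float(bmi[j]),
                gender="F" if female[j] else "M",
                sample_weight=float(weight[j]),
                medical_record_t2d=group == "T2D",
            ))
    return records


def _pick(rng: np.random.Generator, pairs: Sequence[tuple[str, float]]) -> str:
    labels = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def generate_annotation(
    n_gc: int = 142,
    n_lc: int = 144,
    class_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[MetaboliteRecord]:
    """Generate platform-disjoint metabolite annotation records.

    Lipid records in the LPC / carnitine / NEFA sub-classes carry an acyl
    chain descriptor (carbons, double bonds); every record belongs to 1-3
    synthetic pathways drawn mostly from its class's "home" pathways.
    """
    if n_gc < 0 or n_lc < 0:
        raise ConfigurationError("metabolite counts must be non-negative")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class proportions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    classes = sorted(props)
    p = np.array([props[c] for c in classes])
    home_pathways = {c: [f"PW_{c.split()[0][:4]}_{k}" for k in range(_N_PATHWAYS_PER_CLASS)]
                     for c in classes}
    all_pathways = [pw for pws in home_pathways.values() for pw in pws]

    records: list[MetaboliteRecord] = []
    for platform, n_plat, prefix in (("GC-MS", n_gc, "GC"), ("LC-MS", n_lc, "LC")):
        draws = rng.choice(len(classes), size=n_plat, p=p)
        for j in range(n_plat):
            cls = classes[draws[j]]
            local_id = f"{prefix}_{j + 1:04d}"
            sub = None
            acyl = None
            if cls == "lipids and lipid-like molecules":
                sub = _pick(rng, _LIPID_SUBCLASSES)
            elif cls == "amino acids, peptides and analogues":
                sub = _pick(rng, _AA_SUBCLASSES)
            if sub in ("LPC", "carnitine", "NEFA"):
                carbons = int(rng.choice([12, 14, 16, 17, 18, 20, 22]))
                dbonds = int(rng.integers(0, min(6, carbons // 3) + 1))
                acyl = (carbons, dbonds)
                name = f"{sub} ({carbons}:{dbonds}) {local_id}"
            else:
                name = f"{(sub or cls.split()[0]).capitalize()} {local_id}"
            n_pw = int(rng.integers(1, 4))
            pw = list(rng.choice(home_pathways[cls], size=min(n_pw, _N_PATHWAYS_PER_CLASS),
                                 replace=False))
            if rng.random() < 0.2:  # occasional cross-class pathway membership
                pw.append(str(rng.choice(all_pathways)))
            roles_vocab = _ROLES_BY_CLASS.get(cls, ())
            n_roles = int(rng.integers(0, 3)) if roles_vocab else 0
            roles = tuple(rng.choice(roles_vocab, size=min(n_roles, len(roles_vocab)),
                                     replace=False)) if n_roles else ()
            serial = len(records) + 1
            records.append(MetaboliteRecord(
                local_id=local_id,
                name=name,
                hmdb_id=f"HMDB{serial:07d}" if rng.random() < 0.9 else None,
                chebi_id=f"CHEBI:{10000 + serial}" if rng.random() < 0.7 else None,
                kegg_id=f"C{serial:05d}" if rng.random() < 0.6 else None,
                smpdb_ids=(f"SMP{serial:07d}",) if rng.random() < 0.4 else (),
                curated_class=cls,
                sub_class=sub,
                acyl_chain=acyl,
                pathways=tuple(dict.fromkeys(pw)),
                biological_roles=roles,
                platform=platform,
            ))
    return records


def _matches_class(rec: MetaboliteRecord, label: str) -> bool:
    return rec.curated_class == label or rec.sub_class == label


def _missing_mask(rng: np.random.Generator, log2: np.ndarray,
                  spec: MissingnessSpec) -> np.ndarray:
    """Left-censored missingness: P(missing) is a logistic function of the
    within-table intensity rank, calibrated so the mean equals overall_rate."""
    if spec.overall_rate == 0:
        return np.zeros_like(log2, dtype=bool)
    flat = log2.ravel()
    order = flat.argsort().argsort()  # rank 0..N-1
    rank_frac = (order + 0.5) / flat.size
    b = 8.0 * spec.left_censor_weight

    def mean_rate(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a - b * rank_frac)))))

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if mean_rate(mid) < spec.overall_rate:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2
    p_miss = 1.0 / (1.0 + np.exp(-(a - b * rank_frac)))
    return (rng.random(flat.size) < p_miss).reshape(log2.shape)


def generate_intensities(
    samples: Sequence[SampleRecord],
    annotations: Sequence[MetaboliteRecord],
    effects: EffectSpec | None = None,
    missing: MissingnessSpec | None = None,
    corr_spec: Sequence[CorrBlock] | None = None,
    seed: int = 0,
    tissues: Sequence[str] = TISSUES,
) -> SyntheticDataset:
    """Generate raw intensity tables for every (tissue, platform).

    Model: per metabolite-tissue, log2 intensity = mu + sd * z with
    mu ~ U[10, 20], sd ~ U[0.3, 1.2]; z is standard normal with optional
    equicorrelated blocks (shared-factor construction) and additive group
    shifts in SD units, so planted effect sizes read directly as
    standardized differences on the analysis scale.
    """
    effects = effects or EffectSpec()
    missing = missing or MissingnessSpec()
    missing.validate()
    corr_spec = list(corr_spec or [])
    if not samples or not annotations:
        raise ConfigurationError("samples and annotations must be non-empty")

    sample_ids = [s.sample_id for s in samples]
    group = np.array([s.phenotype for s in samples])
    met_ids = [r.local_id for r in annotations]
    by_platform = {p: [r.local_id for r in annotations if r.platform == p]
                   for p in PLATFORMS}
    if any(r.platform not in PLATFORMS for r in annotations):
        raise ConfigurationError("every annotation record needs a platform")

    for e in effects.entries:
        if not any(_matches_class(r, e.metabolite_class) for r in annotations):
            raise ConfigurationError(
                f"effect references class {e.metabolite_class!r} with no members")

    n, m = len(samples), len(met_ids)
    col_of = {mid: j for j, mid in enumerate(met_ids)}
    tables: dict[tuple[str, str], IntensityTable] = {}
    complete: dict[tuple[str, str], pd.DataFrame] = {}
    truth_effects: list[dict] = []
    truth_modules: list[dict] = []

    for t_idx, tissue in enumerate(tissues):
        rng = np.random.default_rng([seed, 7919, t_idx])
        mu = rng.uniform(10, 20, size=m)
        sd = rng.uniform(0.3, 1.2, size=m)
        z = rng.standard_normal((n, m))

        # planted correlation blocks (shared factor per block)
        for b_idx, block in enumerate(b for b in corr_spec if b.tissue == tissue):
            pool = [r.local_id for r in annotations
                    if block.sub_class is None or _matches_class(r, block.sub_class)]
            if len(pool) < block.n_members:
                raise ConfigurationError(
                    f"correlation block in {tissue} needs {block.n_members} members, "
                    f"pool has {len(pool)}")
            members = list(rng.choice(pool, size=block.n_members, replace=False))
            cols = [col_of[mid] for mid in members]
            f = rng.standard_normal(n)
            r = math.sqrt(block.rho)
            z[:, cols] = r * f[:, None] + math.sqrt(1 - block.rho) * z[:, cols]
            if block.shift:
                # shift enters through the shared factor, so each member's
                # marginal standardized shift is block.shift * sqrt(rho)
                mask = _group_mask(group, block.comparison)
                z[np.ix_(mask, cols)] += block.shift * r
            truth_modules.append({
                "tissue": tissue, "members": members, "rho": block.rho,
                "shift": block.shift, "comparison": block.comparison,
                "label": block.label or f"{tissue}_block{b_idx}",
            })

        # planted group effects
        for e in effects.entries:
            if e.tissue != tissue:
                continue
            cols = [col_of[r.local_id] for r in annotations
                    if _matches_class(r, e.metabolite_class)]
            mask = _group_mask(group, e.comparison)
            z[np.ix_(mask, cols)] += e.effect_size
            ref = ~mask
            realized = z[np.ix_(mask, cols)].mean(axis=0) - z[np.ix_(ref, cols)].mean(axis=0)
            truth_effects.append({
                "metabolite_class": e.metabolite_class, "tissue": tissue,
                "comparison": e.comparison, "effect_size": e.effect_size,
                "members": [met_ids[c] for c in cols],
                "realized_mean_shift_sd": float(realized.mean()),
            })

        log2_all = mu[None, :] + sd[None, :] * z
        for p_idx, platform in enumerate(PLATFORMS):
            cols = [col_of[mid] for mid in by_platform[platform]]
            if not cols:
                continue
            sub_log2 = log2_all[:, cols]
            raw = np.power(2.0, sub_log2)
            miss_rng = np.random.default_rng([seed, 104729, t_idx, p_idx])
            miss = _missing_mask(miss_rng, sub_log2, missing)
            raw = raw.astype(float)
            raw[miss] = np.nan
            df = pd.DataFrame(raw.T, index=by_platform[platform], columns=sample_ids)
            tables[(tissue, platform)] = IntensityTable(tissue, platform, df)
            complete[(tissue, platform)] = pd.DataFrame(
                sub_log2.T, index=by_platform[platform], columns=sample_ids)

    truth = {
        "seed": seed,
        "groups": {s.sample_id: s.phenotype for s in samples},
        "effects": truth_effects,
        "modules": truth_modules,
        "missingness": asdict(missing),
    }
    return SyntheticDataset(
        intensity_tables=tables,
        samples=list(samples),
        annotations=list(annotations),
        truth=truth,
        complete_log2=complete,
    )


def _group_mask(group: np.ndarray, comparison: str) -> np.ndarray:
    """Boolean mask of samples whose mean is shifted for this comparison."""
    if comparison == "PD_vs_CTRL":
        return np.isin(group, ("prediabetes", "T2D"))
    return group == "T2D"


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact dialect the ingest module reads.

    Emits one intensity TSV per (tissue, platform), a samples TSV, an
    annotation JSON, the truth JSON, and a manifest with sha256 checksums.
    Returns a mapping from logical names to paths.
    """
    if not dataset.intensity_tables:
        raise MetmapError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        for (tissue, platform), table in sorted(dataset.intensity_tables.items()):
            name = f"intensity_{tissue}_{platform.replace('-', '')}.tsv"
            p = directory / name
            table.values.to_csv(p, sep="\t", index_label="metabolite_id", na_rep="")
            paths[f"intensity/{tissue}/{platform}"] = p

        sdf = pd.DataFrame([asdict(s) for s in dataset.samples])
        p = directory / "samples.tsv"
        sdf.to_csv(p, sep="\t", index=False)
        paths["samples"] = p

        p = directory / "annotations.json"
        with p.open("w") as fh:
            json.dump([r.to_dict() for r in dataset.annotations], fh, indent=1,
                      sort_keys=True)
        paths["annotations"] = p

        p = directory / "truth.json"
        with p.open("w") as fh:
            json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        paths["truth"] = p
    except OSError as exc:
        raise MetmapError(f"failed writing fixture under {directory}: {exc}") from exc

    manifest = {"files": {str(pth.name): _sha256(pth) for pth in paths.values()}}
    mp = directory / "manifest.json"
    with mp.open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = mp
    return paths
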