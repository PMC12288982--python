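"""Synthetic cohorts with the study's data structure and known ground truth.

The generator emulates a three-arm infant cohort — well-nourished controls,
RUSF responders, and nonresponders with a systemically inflamed subgroup —
with four stool time points (9, 12, 13 and 18 months), a 23-marker biomarker
panel, ASV counts with planted taxon shifts, and monthly growth records with
group-specific intervention-window WAZ velocities.

Count model: per-sample Dirichlet-multinomial.  A population-level baseline
Dirichlet concentration vector (drawn once from ``population_seed`` so two
cohorts share a taxon universe) is modulated per sample by exp(log-fold
shifts) keyed on (group, pre/post intervention) and taxon class or family.
Biomarkers are log-normal with group mean shifts in log-sd units.  All
sampling flows through a seeded Generator: regeneration from (spec, seed) is
bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import GrowthRecord
from .data_io import (
    AsvCountTable,
    BiomarkerTable,
    GroupLabel,
    TaxonomyMap,
)
from .errors import ValidationError

#: The nine-marker predictive panel plus the wider screening panel (23 total).
PANEL_9 = (
    "GLP2",
    "MPO",
    "prealbumin",
    "NEO",
    "claudin-15",
    "creatinine",
    "CRP",
    "IL-10",
    "MCP1",
)
EXTRA_MARKERS = (
    "AGP",
    "IL-6",
    "TNF-a",
    "IFN-g",
    "IL-1b",
    "IGF1",
    "leptin",
    "LCN2",
    "IL-8",
    "IL-12",
    "IP-10",
    "ferritin",
    "A1AT",
    "I-FABP",
)
ALL_MARKERS = PANEL_9 + EXTRA_MARKERS

INFLAMMATION_MARKERS = ("CRP", "AGP", "IL-6", "TNF-a", "IFN-g", "IL-1b")

#: Fixed bacterial hierarchy: genus -> (phylum, class, order, family).
_HIERARCHY: dict[str, tuple[str, str, str, str]] = {
    "Bifidobacterium": ("Actinomycetota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Actinomyces": ("Actinomycetota", "Actinomycetia", "Actinomycetales", "Actinomycetaceae"),
    "Escherichia-Shigella": ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Klebsiella": ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Salmonella": ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Haemophilus": ("Pseudomonadota", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae"),
    "Veillonella": ("Bacillota", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Megasphaera": ("Bacillota", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Dialister": ("Bacillota", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Lachnoclostridium": ("Bacillota", "Clostridia", "Lachnospirales", "Lachnospiraceae"),
    "Blautia": ("Bacillota", "Clostridia", "Lachnospirales", "Lachnospiraceae"),
    "Faecalibacterium": ("Bacillota", "Clostridia", "Oscillospirales", "Ruminococcaceae"),
    "Streptococcus": ("Bacillota", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Lactobacillus": ("Bacillota", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Bacteroides": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Prevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
}

REQUIRED_CLASSES = (
    "Actinomycetia",
    "Gammaproteobacteria",
    "Negativicutes",
    "Clostridia",
    "Bacteroidia",
)

PRE_TIMEPOINTS = (9,)
POST_TIMEPOINTS = (12, 13, 18)


@dataclass
class EffectSpec:
    """Planted effects and cohort geometry; defaults are the study conditions.

    Taxon shifts are log-fold modifications of the Dirichlet concentration,
    keyed (group, phase) -> {("class"|"family", name): log-fold}.  Biomarker
    shifts are log-scale mean differences in units of the log-sd.  Growth
    velocities are ΔWAZ/month during the 9-11 month intervention window; the
    responder default sits above the >0.5/month selection cut-off (responders
    were chosen as extreme gainers), the nonresponder default is the reported
    group mean of −0.081/month.
    """

    n_responders: int = 30
    n_nonresponders: int = 30
    n_inflamed: int = 7
    n_controls: int = 28
    timepoints: tuple[int, ...] = (9, 12, 13, 18)

    # microbiome
    n_taxa: int = 150
    dirichlet_concentration: float = 50.0
    depth_mean: float = 60000.0
    depth_log_sd: float = 0.2
    population_seed: int = 0
    taxa_shifts: dict = field(
        default_factory=lambda: {
            ("control", "pre"): {("family", "Bifidobacteriaceae"): 1.5},
            ("control", "post"): {("family", "Bifidobacteriaceae"): 1.5},
            ("responder", "pre"): {("class", "Gammaproteobacteria"): 1.0},
            ("responder", "post"): {
                ("class", "Negativicutes"): 1.2,
                ("class", "Gammaproteobacteria"): -1.0,
            },
        }
    )

    # biomarkers (log-sd units, relative to the nonresponder/wasted baseline)
    marker_log_sd: float = 1.0
    biomarker_shifts: dict = field(
        default_factory=lambda: {
            "responder": {
                "IL-10": 0.8,
                "GLP2": 0.7,
                "prealbumin": 0.7,
                "creatinine": 0.6,
            },
            "nonresponder": {
                "CRP": 0.8,
                "MPO": 0.6,
                "NEO": 0.6,
                "MCP1": 0.5,
                "claudin-15": 0.5,
            },
            "control": {
                "IGF1": 1.0,
                "prealbumin": 0.8,
                "GLP2": 0.8,
                "leptin": 0.8,
                "CRP": -0.6,
                "IL-6": -0.5,
                "TNF-a": -0.5,
                "IFN-g": -0.5,
                "IL-1b": -0.5,
                "LCN2": -0.5,
            },
        }
    )
    inflamed_log_shift: float = 3.0
    missingness: dict = field(default_factory=dict)  # marker -> fraction

    # growth (ΔWAZ/month unless noted)
    intervention_window: tuple[float, float] = (9.0, 11.0)
    velocity_by_group: dict = field(
        default_factory=lambda: {
            "control": -0.02,
            "responder": 0.75,
            "nonresponder": -0.081,
            "inflamed": -0.30,
        }
    )
    velocity_between_sd: float = 0.04
    visit_noise_sd: float = 0.05
    waz_baseline: dict = field(
        default_factory=lambda: {
            "control": 0.3,
            "responder": -2.6,
            "nonresponder": -2.4,
            "inflamed": -1.9,
        }
    )
    intercept_sd: float = 0.3

    #: Published responder mean ΔWAZ over the whole 8-week course; kept for
    #: reference only — its unit convention (per-month vs per-period) clashes
    #: with the >0.5/month selection rule, so it is not the planting default.
    reported_responder_delta_waz_per_period: float = 0.413

    def __post_init__(self) -> None:
        if self.n_inflamed > self.n_nonresponders:
            raise ValidationError("inflamed subgroup cannot exceed the nonresponder group")
        if self.depth_mean <= 0 or self.dirichlet_concentration <= 0:
            raise ValidationError("depths and concentrations must be positive")

    def to_yaml(self, path=None) -> str:
        """Serialize the spec; tuple keys become "a/b" (groups) and "rank:name"."""
        import yaml

        doc = dataclasses.asdict(self)
        doc["taxa_shifts"] = {
            f"{g}/{phase}": {f"{rank}:{name}": v for (rank, name), v in shifts.items()}
            for (g, phase), shifts in self.taxa_shifts.items()
        }
        doc["timepoints"] = list(self.timepoints)
        doc["intervention_window"] = list(self.intervention_window)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "EffectSpec":
        import yaml
        from pathlib import Path

        text = str(source)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        doc = yaml.safe_load(text)
        doc["taxa_shifts"] = {
            tuple(key.split("/", 1)): {
                tuple(inner.split(":", 1)): v for inner, v in shifts.items()
            }
            for key, shifts in doc.get("taxa_shifts", {}).items()
        }
        doc["timepoints"] = tuple(doc.get("timepoints", (9, 12, 13, 18)))
        doc["intervention_window"] = tuple(doc.get("intervention_window", (9.0, 11.0)))
        return cls(**doc)

    @classmethod
    def null(cls) -> "EffectSpec":
        """All planted effects zeroed: no group should be detectable."""
        return cls(
            taxa_shifts={},
            biomarker_shifts={},
            inflamed_log_shift=0.0,
            velocity_by_group={g: 0.0 for g in ("control", "responder", "nonresponder", "inflamed")},
            waz_baseline={g: -1.0 for g in ("control", "responder", "nonresponder", "inflamed")},
        )


@dataclass
class SyntheticCohort:
    biomarkers: BiomarkerTable
    asv: AsvCountTable
    taxonomy: TaxonomyMap
    growth: dict[str, GrowthRecord]
    labels: pd.DataFrame  # index subject_id; columns group, inflamed
    spec: EffectSpec
    seed: int

    def group_of(self, subject: str) -> GroupLabel:
        row = self.labels.loc[subject]
        return GroupLabel(str(row["group"]), bool(row["inflamed"]))

    def labels_for(self, index: pd.Index) -> pd.Series:
        """Group label aligned to a (subject, timepoint) MultiIndex."""
        subjects = index.get_level_values("subject_id")
        return pd.Series(self.labels["group"].reindex(subjects).to_numpy(), index=index)


# ---------------------------------------------------------------------------


def _subject_frame(spec: EffectSpec, rng: np.random.Generator) -> pd.DataFrame:
    ids = (
        [f"R{i + 1:02d}" for i in range(spec.n_responders)]
        + [f"N{i + 1:02d}" for i in range(spec.n_nonresponders)]
        + [f"C{i + 1:02d}" for i in range(spec.n_controls)]
    )
    groups = (
        ["responder"] * spec.n_responders
        + ["nonresponder"] * spec.n_nonresponders
        + ["control"] * spec.n_controls
    )
    labels = pd.DataFrame({"group": groups}, index=pd.Index(ids, name="subject_id"))
    labels["inflamed"] = False
    nr_ids = labels.index[labels["group"] == "nonresponder"]
    inflamed = rng.choice(nr_ids, size=spec.n_inflamed, replace=False)
    labels.loc[inflamed, "inflamed"] = True
    return labels


def gen_taxonomy(n_taxa: int = 150, seed: int = 0) -> TaxonomyMap:
    """Random ASV-to-lineage map over a fixed bacterial hierarchy.

    Every genus of the hierarchy (hence all five focal classes) receives at
    least one ASV; the remainder are assigned by weighted draw.
    """
    if n_taxa < 20:
        raise ValidationError("need at least 20 taxa")
    rng = np.random.default_rng(seed)
    genera = list(_HIERARCHY)
    weights = np.ones(len(genera))
    # gut-realistic skew: infant guts are Bifidobacterium/Enterobacteriaceae heavy
    for i, g in enumerate(genera):
        if g in ("Bifidobacterium", "Escherichia-Shigella", "Veillonella", "Bacteroides"):
            weights[i] = 3.0
    weights = weights / weights.sum()
    assignments = genera + list(
        rng.choice(genera, size=n_taxa - len(genera), p=weights)
    )
    rng.shuffle(assignments)
    rows = []
    for i, genus in enumerate(assignments):
        phylum, cls, order, family = _HIERARCHY[genus]
        rows.append((f"ASV{i + 1:04d}", phylum, cls, order, family, genus))
    df = pd.DataFrame(
        rows, columns=["asv_id", "phylum", "class", "order", "family", "genus"]
    ).set_index("asv_id")
    return TaxonomyMap(df)


def _baseline_alpha(spec: EffectSpec, taxonomy: TaxonomyMap) -> np.ndarray:
    """Population baseline Dirichlet concentrations (shared across cohorts)."""
    rng = np.random.default_rng(spec.population_seed + 1)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(taxonomy.data))
    return raw / raw.sum() * spec.dirichlet_concentration


def _shift_vector(
    spec: EffectSpec, taxonomy: TaxonomyMap, group: str, timepoint: int
) -> np.ndarray:
    phase = "pre" if timepoint in PRE_TIMEPOINTS else "post"
    shifts = spec.taxa_shifts.get((group, phase), {})
    out = np.zeros(len(taxonomy.data))
    for (rank, name), logfold in shifts.items():
        mask = (taxonomy.data[rank] == name).to_numpy()
        out[mask] += logfold
    return out


def gen_asv_counts(
    labels: pd.DataFrame,
    spec: EffectSpec,
    seed: int = 0,
    taxonomy: TaxonomyMap | None = None,
) -> AsvCountTable:
    """Dirichlet-multinomial ASV counts for every (subject, timepoint)."""
    if taxonomy is None:
        taxonomy = gen_taxonomy(spec.n_taxa, spec.population_seed)
    rng = np.random.default_rng(seed)
    alpha0 = _baseline_alpha(spec, taxonomy)
    asv_ids = list(taxonomy.data.index)
    rows, keys = [], []
    for subject in labels.index:
        group = str(labels.at[subject, "group"])
        for tp in spec.timepoints:
            alpha = alpha0 * np.exp(_shift_vector(spec, taxonomy, group, tp))
            p = rng.dirichlet(alpha)
            depth = int(
                np.round(rng.lognormal(np.log(spec.depth_mean), spec.depth_log_sd))
            )
            rows.append(rng.multinomial(max(depth, 1), p))
            keys.append((subject, tp))
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.MultiIndex.from_tuples(keys, names=["subject_id", "timepoint"]),
        columns=asv_ids,
    )
    return AsvCountTable(df)


def gen_biomarkers(
    labels: pd.DataFrame, spec: EffectSpec, seed: int = 0
) -> BiomarkerTable:
    """Log-normal 23-marker panel at the 9-month pre-intervention visit.

    Group-level shifts act on the log scale in sd units; the inflamed
    nonresponder subgroup gets an extra shift on the systemic-inflammation
    markers.  Optional per-marker missingness supports filter testing.
    """
    rng = np.random.default_rng(seed)
    base_log = {m: float(2.0 + 0.1 * i) for i, m in enumerate(ALL_MARKERS)}
    rows, keys = [], []
    for subject in labels.index:
        group = str(labels.at[subject, "group"])
        inflamed = bool(labels.at[subject, "inflamed"])
        shifts = spec.biomarker_shifts.get(group, {})
        vals = []
        for m in ALL_MARKERS:
            mu = base_log[m] + shifts.get(m, 0.0) * spec.marker_log_sd
            if inflamed and m in INFLAMMATION_MARKERS:
                mu += spec.inflamed_log_shift * spec.marker_log_sd
            vals.append(np.exp(rng.normal(mu, spec.marker_log_sd)))
        rows.append(vals)
        keys.append((subject, 9))
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=["subject_id", "timepoint"]),
        columns=list(ALL_MARKERS),
    )
    for marker, frac in spec.missingness.items():
        mask = rng.random(len(df)) < frac
        df.loc[mask, marker] = np.nan
    return BiomarkerTable(df)


def _piecewise_waz(
    spec: EffectSpec,
    group_key: str,
    intercept: float,
    velocity: float,
    ages: np.ndarray,
) -> np.ndarray:
    """Mean WAZ trajectory: pre-intervention drift to the 9-month baseline,
    planted intervention-window velocity, then group-specific follow-up."""
    t0, t1 = spec.intervention_window
    baseline = spec.waz_baseline.get(group_key, -1.0) + intercept
    if group_key == "control":
        return baseline + spec.velocity_by_group.get("control", 0.0) * (ages - t0)
    pre_slope = (baseline - (baseline + 1.0)) / t0  # drift down ~1 z from birth
    post_slope = {"responder": 0.10, "nonresponder": 0.08, "inflamed": 0.08}.get(group_key, 0.0)
    waz = np.empty_like(ages, dtype=float)
    for i, a in enumerate(ages):
        if a <= t0:
            waz[i] = baseline + pre_slope * (a - t0)
        elif a <= t1:
            waz[i] = baseline + velocity * (a - t0)
        elif a <= 13.0:
            waz[i] = baseline + velocity * (t1 - t0)
        else:
            waz[i] = baseline + velocity * (t1 - t0) + post_slope * (a - 13.0)
    return waz


def gen_growth(
    labels: pd.DataFrame, spec: EffectSpec, seed: int = 0
) -> dict[str, GrowthRecord]:
    """Monthly WAZ/WLZ/LAZ records from 0 to 24 months per subject."""
    rng = np.random.default_rng(seed)
    ages = np.arange(0.0, 25.0)
    records: dict[str, GrowthRecord] = {}
    for subject in labels.index:
        group = str(labels.at[subject, "group"])
        inflamed = bool(labels.at[subject, "inflamed"])
        key = "inflamed" if (group == "nonresponder" and inflamed) else group
        intercept = rng.normal(0.0, spec.intercept_sd)
        velocity = rng.normal(
            spec.velocity_by_group.get(key, 0.0), spec.velocity_between_sd
        )
        waz = _piecewise_waz(spec, key, intercept, velocity, ages)
        waz = waz + rng.normal(0.0, spec.visit_noise_sd, size=len(ages))
        wlz = waz - 0.1 + rng.normal(0.0, 0.15, size=len(ages))
        laz_base = -0.5 if group == "control" else -1.8
        laz = laz_base + rng.normal(0.0, 0.2, size=len(ages))
        obs = pd.DataFrame({"age_months": ages, "waz": waz, "wlz": wlz, "laz": laz})
        records[subject] = GrowthRecord(subject, obs)
    return records


def generate_cohort(spec: EffectSpec | None = None, seed: int = 0) -> SyntheticCohort:
    """Full cohort bundle; bit-identical regeneration for a fixed (spec, seed)."""
    spec = spec if spec is not None else EffectSpec()
    ss = np.random.SeedSequence(seed)
    s_labels, s_asv, s_bio, s_growth = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)]
    taxonomy = gen_taxonomy(spec.n_taxa, spec.population_seed)
    labels = _subject_frame(spec, np.random.default_rng(s_labels))
    return SyntheticCohort(
        biomarkers=gen_biomarkers(labels, spec, s_bio),
        asv=gen_asv_counts(labels, spec, s_asv, taxonomy),
        taxonomy=taxonomy,
        growth=gen_growth(labels, spec, s_growth),
        labels=labels,
        spec=spec,
        seed=seed,
    )
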