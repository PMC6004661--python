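"""Synthetic spontaneous-report generator and published study marginals.

Two distinct testing resources live here:

* :func:`simulate` draws a JADER-dialect report set with *known* ground
  truth.  Risk multipliers act on the probability that an exposed report
  lists a target PT — i.e. on relative reporting, not biological incidence —
  because that relative reporting ratio is exactly what disproportionality
  statistics estimate, making the injected multiplier the estimand.  Every
  simulated report carries at least one event (spontaneous reports exist
  only because something was reported), and missingness is applied last so
  the inclusion filters have something to do.

* :func:`study_tables` returns the 2x2 tables reconstructed from the
  printed marginal counts of the incretin/GERD disproportionality study on
  the Japanese adverse-event database (38,887 analyzable diabetic-patient
  reports, 2004-2015; 654 reports with GERD-like symptoms).  These
  counts-level fixtures let every printed ROR/IC value be recomputed
  exactly without access to the raw database.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .contingency import ContingencyTable, table_from_marginals
from .reports import (
    DECADE_BUCKETS,
    Dialect,
    DrugEntry,
    EventEntry,
    ReportRecord,
    ReportSet,
    write_report_set,
)

EPOCH = datetime.date(2004, 1, 1)
WINDOW_DAYS = (datetime.date(2015, 12, 31) - EPOCH).days

QUALITATIVE_AGES = ("elderly", "youth", "adult")


@dataclass(frozen=True)
class DrugSpec:
    name: str
    drug_class: str
    exposure_prob: float  # probability of appearing as a suspect drug
    concomitant_prob: float = 0.0


@dataclass(frozen=True)
class EventSpec:
    pt_id: str
    pt_name: str
    baseline_prob: float  # per-report reporting probability when unexposed


@dataclass(frozen=True)
class RiskEffect:
    """Relative reporting risk injected for (drug or class) x PT subset.

    ``multiplier`` scales the reporting probability of the listed PTs on
    reports exposed to the drug/class.  When ``older_multiplier`` is given,
    reports in decade buckets at or above ``age_threshold`` use it instead,
    which lets tests inject stratum-dependent ground truth.
    """

    drug_or_class: str
    pt_ids: frozenset[str]
    multiplier: float
    older_multiplier: float | None = None
    age_threshold: int = 70


@dataclass
class SimConfig:
    """Full parameterization of the generator.

    Defaults follow :func:`default_config`, which emulates the analyzed
    study population (its size, sex split, age profile, incretin exposure
    frequencies and GERD-PT reporting rates).
    """

    n_reports: int
    seed: int
    sex_split_male: float
    age_bucket_probs: dict[str, float]
    primary_disease_probs: dict[str, float]
    drugs: list[DrugSpec]
    events: list[EventSpec]
    risk_effects: list[RiskEffect] = field(default_factory=list)
    onset_weibull: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"other": (1.0, 120.0)}
    )  # class -> (shape, scale days)
    duration_lognorm: tuple[float, float] = (math.log(90.0), 1.0)
    missing_sex_rate: float = 0.0
    missing_age_rate: float = 0.0
    qualitative_age_rate: float = 0.0
    missing_date_rate: float = 0.0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        rates = {
            "sex_split_male": self.sex_split_male,
            "missing_sex_rate": self.missing_sex_rate,
            "missing_age_rate": self.missing_age_rate,
            "qualitative_age_rate": self.qualitative_age_rate,
            "missing_date_rate": self.missing_date_rate,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.age_bucket_probs.values()) - 1.0) > 1e-9:
            raise ValueError("age_bucket_probs must sum to 1")
        for b in self.age_bucket_probs:
            if b not in DECADE_BUCKETS:
                raise ValueError(f"unknown age bucket {b!r}")
        for d in self.drugs:
            if not 0.0 <= d.exposure_prob <= 1.0 or not 0.0 <= d.concomitant_prob <= 1.0:
                raise ValueError(f"drug {d.name}: probabilities must lie in [0, 1]")
        for e in self.events:
            if not 0.0 <= e.baseline_prob <= 1.0:
                raise ValueError(f"event {e.pt_id}: baseline_prob must lie in [0, 1]")
        if not self.events:
            raise ValueError("at least one event PT is required")
        for eff in self.risk_effects:
            if eff.multiplier < 0 or (
                eff.older_multiplier is not None and eff.older_multiplier < 0
            ):
                raise ValueError("risk multipliers must be >= 0")

    def content_hash(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=sorted)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(config: SimConfig, seed: int | None = None) -> ReportSet:
    """Draw a report set; deterministic given the seed.

    Generation order: demographics -> primary diseases -> drug exposures
    with start/end dates -> events (baseline probability times any matching
    risk multiplier, capped at 1) -> onset dates (drug start plus a Weibull
    latency for drug-attributed events) -> missingness.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drugs = config.drugs
    events = config.events

    sex = np.where(rng.random(n) < config.sex_split_male, "male", "female").astype(object)
    buckets = list(config.age_bucket_probs)
    age = rng.choice(np.array(buckets, dtype=object), size=n, p=list(config.age_bucket_probs.values()))
    low_map = {b: 10 * DECADE_BUCKETS.index(b) for b in buckets}
    age_low = np.array([low_map[b] for b in age])

    disease_names = list(config.primary_disease_probs)
    disease_mat = rng.random((n, len(disease_names))) < np.array(
        list(config.primary_disease_probs.values())
    )

    n_drugs = len(drugs)
    suspect = rng.random((n, n_drugs)) < np.array([d.exposure_prob for d in drugs])
    concomitant = rng.random((n, n_drugs)) < np.array(
        [d.concomitant_prob for d in drugs]
    )
    concomitant &= ~suspect  # one role per (report, drug)
    start_day = rng.integers(0, WINDOW_DAYS - 400, size=(n, n_drugs))
    mu, sigma = config.duration_lognorm
    duration = np.maximum(1, rng.lognormal(mu, sigma, size=(n, n_drugs)).astype(int))

    # per-report reference start: earliest suspect start among any drugs
    any_suspect = suspect.any(axis=1)
    masked_starts = np.where(suspect, start_day, np.iinfo(np.int64).max)
    ref_start = np.where(any_suspect, masked_starts.min(axis=1), rng.integers(0, WINDOW_DAYS - 400, n))

    older = age_low >= 70

    base = np.array([e.baseline_prob for e in events])
    p_evt = np.tile(base, (n, 1))
    # class -> columns of member drugs; name matches too
    attributed_class = np.full((n, len(events)), "", dtype=object)
    for eff in config.risk_effects:
        drug_cols = [
            j for j, d in enumerate(drugs)
            if d.drug_class == eff.drug_or_class or d.name == eff.drug_or_class
        ]
        if not drug_cols:
            continue
        pt_cols = [j for j, e in enumerate(events) if e.pt_id in eff.pt_ids]
        exposed_rows = suspect[:, drug_cols].any(axis=1)
        mult = np.full(n, eff.multiplier)
        if eff.older_multiplier is not None:
            mult = np.where(older, eff.older_multiplier, eff.multiplier)
        rows = np.nonzero(exposed_rows)[0]
        p_evt[np.ix_(rows, pt_cols)] *= mult[rows, None]
        # record which class drives the latency of attributed events
        cls = drugs[drug_cols[0]].drug_class
        for j in pt_cols:
            attributed_class[rows, j] = cls
    np.clip(p_evt, 0.0, 1.0, out=p_evt)

    evt_mat = rng.random((n, len(events))) < p_evt
    # every spontaneous report must list at least one event; the fallback
    # draw uses the report's own risk-adjusted probabilities so injected
    # multipliers survive conditioning on "something was reported"
    empty = np.nonzero(~evt_mat.any(axis=1))[0]
    if empty.size:
        weights = p_evt[empty]
        cum = np.cumsum(weights, axis=1)
        u = rng.random(empty.size) * cum[:, -1]
        fallback = (cum < u[:, None]).sum(axis=1)
        evt_mat[empty, fallback] = True

    # onset latencies; drug-attributed events anchor at the earliest suspect
    # start of the attributing class so derived times recover the latency model
    onset_day = np.zeros((n, len(events)), dtype=int)
    rows_i, cols_j = np.nonzero(evt_mat)
    class_cols = {}
    for j, d in enumerate(drugs):
        class_cols.setdefault(d.drug_class, []).append(j)
    for cls in set(attributed_class[rows_i, cols_j]) | {""}:
        mask = attributed_class[rows_i, cols_j] == cls
        if not mask.any():
            continue
        if cls and cls in config.onset_weibull:
            shape, scale = config.onset_weibull[cls]
        elif "other" in config.onset_weibull:
            shape, scale = config.onset_weibull["other"]
        else:
            shape, scale = 1.0, 120.0
        rows = rows_i[mask]
        if cls and cls in class_cols:
            cls_starts = np.where(
                suspect[np.ix_(rows, class_cols[cls])],
                start_day[np.ix_(rows, class_cols[cls])],
                np.iinfo(np.int64).max,
            ).min(axis=1)
            anchor = np.where(cls_starts < np.iinfo(np.int64).max, cls_starts, ref_start[rows])
        else:
            anchor = ref_start[rows]
        lat = np.maximum(1, (scale * rng.weibull(shape, size=int(mask.sum()))).astype(int))
        onset_day[rows, cols_j[mask]] = anchor + lat

    # missingness masks (applied last)
    miss_sex = rng.random(n) < config.missing_sex_rate
    qual_age = rng.random(n) < config.qualitative_age_rate
    miss_age = rng.random(n) < config.missing_age_rate
    qual_word = rng.choice(np.array(QUALITATIVE_AGES, dtype=object), size=n)
    miss_start = rng.random((n, n_drugs)) < config.missing_date_rate
    miss_end = rng.random((n, n_drugs)) < config.missing_date_rate
    miss_onset = rng.random((n, len(events))) < config.missing_date_rate

    events_by_row: dict[int, list[EventEntry]] = {}
    for i, j in zip(rows_i.tolist(), cols_j.tolist()):
        od = None
        if not miss_onset[i, j]:
            od = EPOCH + datetime.timedelta(days=int(onset_day[i, j]))
        events_by_row.setdefault(i, []).append(
            EventEntry(pt_id=events[j].pt_id, pt_name=events[j].pt_name, onset_date=od)
        )

    records = []
    width = len(str(n))
    for i in range(n):
        drug_entries = []
        for j in range(n_drugs):
            if suspect[i, j] or concomitant[i, j]:
                s = int(start_day[i, j])
                sd = None if miss_start[i, j] else EPOCH + datetime.timedelta(days=s)
                ed = (
                    None
                    if miss_end[i, j] or sd is None
                    else EPOCH + datetime.timedelta(days=s + int(duration[i, j]))
                )
                drug_entries.append(
                    DrugEntry(
                        drug_name=drugs[j].name,
                        role="suspect" if suspect[i, j] else "concomitant",
                        start_date=sd,
                        end_date=ed,
                    )
                )
        if qual_age[i]:
            age_val = str(qual_word[i])
        elif miss_age[i]:
            age_val = None
        else:
            age_val = str(age[i])
        records.append(
            ReportRecord(
                case_id=f"C{i:0{width}d}",
                sex=None if miss_sex[i] else str(sex[i]),
                age_bucket=age_val,
                primary_diseases=frozenset(
                    disease_names[k] for k in np.nonzero(disease_mat[i])[0]
                ),
                drugs=tuple(drug_entries),
                events=tuple(events_by_row.get(i, ())),
            )
        )
    return ReportSet(records)


def simulate_to_files(config: SimConfig, outdir, dialect: Dialect | None = None) -> dict:
    """Simulate and write the four-table layout plus a run manifest."""
    from pathlib import Path

    reports = simulate(config)
    paths = write_report_set(reports, outdir, dialect=dialect)
    manifest = {
        "seed": config.seed,
        "n_reports": config.n_reports,
        "config_hash": config.content_hash(),
    }
    mpath = Path(outdir) / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths


# ---------------------------------------------------------------------------
# Study-conditions default configuration
# ---------------------------------------------------------------------------

#: GERD-like-symptom PTs that appear in the default event pool, with
#: baseline reporting probabilities matched to the study's event totals.
_GERD_EVENTS = [
    EventSpec("10047700", "Vomiting", 321 / 38887),
    EventSpec("10028813", "Nausea", 293 / 38887),
    EventSpec("10021518", "Impaired gastric emptying", 2 / 38887),
    EventSpec("10030201", "Oesophageal ulcer", 17 / 38887),
    EventSpec("10017885", "Gastrooesophageal reflux disease", 18 / 38887),
    EventSpec("10013950", "Dysphagia", 23 / 38887),
    EventSpec("10000060", "Abdominal distension", 32 / 38887),
    EventSpec("10063655", "Erosive oesophagitis", 25 / 38887),
    EventSpec("10013946", "Dyspepsia", 44 / 38887),
]

_BACKGROUND_EVENTS = [
    EventSpec("10020993", "Hypoglycaemia", 0.12),
    EventSpec("10022611", "Interstitial lung disease", 0.04),
    EventSpec("10037844", "Rash", 0.06),
    EventSpec("10019670", "Hepatic function abnormal", 0.05),
    EventSpec("10069339", "Acute kidney injury", 0.04),
    EventSpec("10013573", "Dizziness", 0.03),
    EventSpec("10012735", "Diarrhoea", 0.05),
]

_GERD_POOL_IDS = frozenset(e.pt_id for e in _GERD_EVENTS)


def default_config(n_reports: int = 38_887, seed: int = 0) -> SimConfig:
    """Generator parameterized to the analyzed study population.

    Sex split and age profile follow the study's demographic table; incretin
    exposure probabilities equal each drug's report share; GERD-PT baseline
    reporting rates equal the study's unexposed event shares; and the
    injected class-level relative reporting risks equal the observed class
    RORs (5.6 for GLP-1 receptor agonists, 0.54 for DPP-4 inhibitors), so
    the default data set behaves like the study that the generator emulates.
    Onset latencies are Weibull with medians of about six weeks (GLP-1-RAs)
    versus about three and a half months (DPP-4-Is), reflecting the earlier
    onset observed for GLP-1-RAs.
    """
    age_totals = {
        "0-9": 40, "10-19": 86, "20-29": 215, "30-39": 748, "40-49": 1990,
        "50-59": 5115, "60-69": 11399, "70-79": 13178, "80-89": 5568, "90+": 548,
    }
    n_total = sum(age_totals.values())
    drugs = [
        DrugSpec("dulaglutide", "GLP-1-RAs", 20 / 38887),
        DrugSpec("exenatide", "GLP-1-RAs", 122 / 38887),
        DrugSpec("liraglutide", "GLP-1-RAs", 278 / 38887),
        DrugSpec("lixisenatide", "GLP-1-RAs", 12 / 38887),
        DrugSpec("alogliptin", "DPP-4-Is", 345 / 38887),
        DrugSpec("anagliptin", "DPP-4-Is", 72 / 38887),
        DrugSpec("linagliptin", "DPP-4-Is", 332 / 38887),
        DrugSpec("omarigliptin", "DPP-4-Is", 2 / 38887),
        DrugSpec("saxagliptin", "DPP-4-Is", 70 / 38887),
        DrugSpec("sitagliptin", "DPP-4-Is", 1181 / 38887),
        DrugSpec("teneligliptin", "DPP-4-Is", 98 / 38887),
        DrugSpec("trelagliptin", "DPP-4-Is", 19 / 38887),
        DrugSpec("vildagliptin", "DPP-4-Is", 1189 / 38887),
        DrugSpec("metformin", "biguanides", 0.05, concomitant_prob=0.10),
        DrugSpec("insulin glargine", "insulins", 0.04, concomitant_prob=0.05),
    ]
    return SimConfig(
        n_reports=n_reports,
        seed=seed,
        sex_split_male=23_669 / 38_887,
        age_bucket_probs={b: v / n_total for b, v in age_totals.items()},
        primary_disease_probs={
            "type 2 diabetes mellitus": 0.95,
            "hypertension": 0.30,
            "dyslipidaemia": 0.20,
        },
        drugs=drugs,
        events=_GERD_EVENTS + _BACKGROUND_EVENTS,
        risk_effects=[
            RiskEffect("GLP-1-RAs", _GERD_POOL_IDS, 5.6),
            RiskEffect("DPP-4-Is", _GERD_POOL_IDS, 0.54),
        ],
        onset_weibull={
            "GLP-1-RAs": (1.0, 60.0),
            "DPP-4-Is": (1.0, 150.0),
            "other": (1.0, 120.0),
        },
        missing_sex_rate=0.05,
        missing_age_rate=0.05,
        qualitative_age_rate=0.02,
        missing_date_rate=0.30,
    )


# ---------------------------------------------------------------------------
# Published marginal counts of the incretin/GERD study
# ---------------------------------------------------------------------------

STUDY_N = 38_887  # analyzable diabetic-patient reports, 2004-2015
STUDY_GERD_TOTAL = 654  # reports listing any GERD-like-symptom PT

#: drug or class -> (n11, n1+) against the pooled 36-PT GERD query
STUDY_DRUG_MARGINALS: dict[str, tuple[int, int]] = {
    "GLP-1-RAs(ALL)": (36, 429),
    "dulaglutide": (1, 20),
    "exenatide": (19, 122),
    "liraglutide": (15, 278),
    "lixisenatide": (1, 12),
    "DPP-4-Is(ALL)": (31, 3276),
    "alogliptin": (1, 345),
    "anagliptin": (0, 72),
    "linagliptin": (4, 332),
    "omarigliptin": (0, 2),
    "saxagliptin": (0, 70),
    "sitagliptin": (16, 1181),
    "teneligliptin": (0, 98),
    "trelagliptin": (1, 19),
    "vildagliptin": (9, 1189),
}

#: per-PT rows: name -> (GLP-1 n11, DPP-4 n11, event total n+1)
STUDY_PT_MARGINALS: dict[str, tuple[int, int, int]] = {
    "Vomiting": (23, 12, 344),
    "Nausea": (17, 9, 310),
    "Impaired gastric emptying": (1, 0, 3),
    "Oesophageal ulcer": (1, 0, 18),
    "Gastrooesophageal reflux disease": (1, 6, 24),
    "Dysphagia": (1, 5, 28),
    "Abdominal distension": (1, 1, 33),
    "Erosive oesophagitis": (0, 1, 25),
    "Dyspepsia": (0, 1, 45),
}

_CLASS_N1PLUS = {"GLP-1-RAs": 429, "DPP-4-Is": 3276}

#: sex -> (GERD-like cases, report total)
STUDY_SEX_MARGINALS = {"male": (363, 23_669), "female": (291, 15_218)}

#: decade bucket -> (GERD-like cases, report total)
STUDY_AGE_MARGINALS = {
    "0-9": (0, 40), "10-19": (1, 86), "20-29": (3, 215), "30-39": (11, 748),
    "40-49": (39, 1990), "50-59": (85, 5115), "60-69": (204, 11_399),
    "70-79": (213, 13_178), "80-89": (87, 5568), "90+": (11, 548),
}


def study_tables() -> dict[str, ContingencyTable]:
    """2x2 tables for every drug/class/PT row with printed marginals.

    Keys: drug and class labels for the pooled GERD query, plus
    ``"<class>:<PT name>"`` for the per-PT rows.
    """
    tables: dict[str, ContingencyTable] = {}
    for label, (n11, n1p) in STUDY_DRUG_MARGINALS.items():
        tables[label] = table_from_marginals(n11, n1p, STUDY_GERD_TOTAL, STUDY_N)
    for pt, (glp, dpp, total) in STUDY_PT_MARGINALS.items():
        tables[f"GLP-1-RAs:{pt}"] = table_from_marginals(
            glp, _CLASS_N1PLUS["GLP-1-RAs"], total, STUDY_N
        )
        tables[f"DPP-4-Is:{pt}"] = table_from_marginals(
            dpp, _CLASS_N1PLUS["DPP-4-Is"], total, STUDY_N
        )
    return tables
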