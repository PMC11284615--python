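"""Deterministic synthetic SEND study bundles with planted ground truth.

Real SEND submissions are confidential, so everything in this package is
exercised against generated studies that emulate the shape of a repeat-dose
rodent toxicology study: a trial summary (TS), trial sets with a vehicle
control group (TX), demographics with birth dates (DM), daily-dose exposure
(EX), disposition (DS), dosing epochs (SE), body weights (BW), clinical
chemistry drawn from known normal distributions (LB), and terminal
microscopic findings with planted incidence counts (MI).

Every quantity a downstream module should recover — which animals are
negative controls, their sex/species/strain/route/ages, each finding's phase,
per-(specimen, finding) affected counts, each lab test's (mu, sigma, n) — is
recorded in a :class:`GroundTruth` serialized beside the study folder.
Identical seeds produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .manifest import load_manifest
from .xpt import DomainTable, VariableMeta, write_xpt

__all__ = [
    "TrialSetSpec", "EpochSpec", "MIPlan", "LBPlan", "StudySpec", "GroundTruth",
    "make_study", "make_default_root", "make_usecase2_fixture", "make_ct_fixture",
]


@dataclass(frozen=True)
class TrialSetSpec:
    setcd: str
    label: str
    n: int
    tcntrl: str | None = None  # None => treated / unlabelled set
    dose: float = 0.0


@dataclass(frozen=True)
class EpochSpec:
    label: str
    start_day: int
    end_day: int | None  # None => open-ended (last epoch)


@dataclass(frozen=True)
class MIPlan:
    specimen: str
    finding: str
    n_affected: int
    severity: str = "MINIMAL"


@dataclass(frozen=True)
class LBPlan:
    testcd: str
    test: str
    spec: str
    units: str
    mean: float
    sd: float
    days: tuple[int, ...] = (28,)


def _default_sets():
    return (
        TrialSetSpec("VEH", "Vehicle Control", 10, "VEHICLE CONTROL", 0.0),
        TrialSetSpec("LD", "Low Dose", 10, None, 10.0),
        TrialSetSpec("MD", "Mid Dose", 10, None, 50.0),
        TrialSetSpec("HD", "High Dose", 10, None, 250.0),
    )


def _default_epochs():
    return (
        EpochSpec("SCREENING", -14, 1),
        EpochSpec("TREATMENT", 1, 29),
        EpochSpec("RECOVERY", 29, None),
    )


@dataclass
class StudySpec:
    """Everything needed to realize one synthetic study deterministically."""

    seed: int
    studyid: str = "SYN001"
    design: str = "PARALLEL"
    start_date: str = "2018-07-15"  # RFSTDTC / STSTDTC (ISO date)
    species: str = "RAT"
    strain: str = "SPRAGUE-DAWLEY"
    route: str = "ORAL GAVAGE"
    sets: tuple[TrialSetSpec, ...] = field(default_factory=_default_sets)
    epochs: tuple[EpochSpec, ...] = field(default_factory=_default_epochs)
    mi_plans: tuple[MIPlan, ...] = (
        MIPlan("LIVER", "NECROSIS", 2, "MILD"),
        MIPlan("LUNG/BRONCHUS", "CELLULARITY, INCREASED", 3),
    )
    examined_specimens: tuple[str, ...] = ("LIVER", "LUNG/BRONCHUS")
    mi_day: int = 28
    lb_plans: tuple[LBPlan, ...] = (
        LBPlan("ALT", "Alanine Aminotransferase", "SERUM", "U/L", 50.0, 5.0),
    )
    bw_days: tuple[int, ...] = (1, 8, 15, 22, 29, 36, 43, 50)
    bw_mean: float = 250.0
    bw_sd: float = 20.0
    age_range: tuple[int, int] = (60, 240)  # age at study day 1, days
    ages: tuple[int, ...] | None = None  # explicit ages cycled over subjects
    n_not_done: int = 1  # controls whose first specimen exam is NOT DONE
    omit_se: bool = False
    omit_tcntrl: bool = False  # drop TCNTRL rows (uncertain-control study)
    species_in_ts_only: bool = False  # blank DM.SPECIES/STRAIN (TS fallback)

    def validate(self) -> None:
        n_controls = sum(s.n for s in self.sets if s.tcntrl is not None) \
            or (self.sets[0].n if self.sets else 0)
        for plan in self.mi_plans:
            if plan.n_affected > n_controls:
                raise ValidationError(
                    f"{self.studyid}: {plan.finding}: {plan.n_affected} affected "
                    f"exceeds {n_controls} control animals"
                )
            if plan.specimen not in self.examined_specimens:
                raise ValidationError(
                    f"{self.studyid}: planned specimen {plan.specimen!r} "
                    "not in examined_specimens"
                )
        if any(s.n <= 0 for s in self.sets):
            raise ValidationError(f"{self.studyid}: set sizes must be positive")
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            raise ValidationError(f"{self.studyid}: bad age_range {self.age_range}")


@dataclass
class GroundTruth:
    """Planted quantities, derivable from the StudySpec alone."""

    studyid: str
    control_ids: list[str]            # retrievable with incl_uncertain=False
    uncertain_ids: list[str]          # additionally retrievable with True
    subjects: dict[str, dict]         # usubjid -> sex/species/strain/route/...
    mi_affected: dict[str, int]       # "SPECIMEN|FINDING" -> distinct controls
    mi_examined: dict[str, int]       # specimen -> examined controls
    mi_phase: str                     # phase class of the planted MI findings
    lb: dict[str, dict]               # testcd -> {mean, sd, units, n}
    n_dm_rows: int

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# table assembly helpers
# ---------------------------------------------------------------------------

def _domain_table(domain: str, records: list[dict]) -> DomainTable:
    variables = [
        VariableMeta(name, label, kind, 8 if kind == "numeric" else 1)
        for name, kind, label in load_manifest()[domain]
    ]
    full = []
    for rec in records:
        row = {
            v.name: (None if v.kind == "numeric" else "") for v in variables
        }
        row.update(rec)
        row.setdefault("DOMAIN", domain)
        row["DOMAIN"] = domain
        full.append(row)
    return DomainTable(domain=domain, variables=variables, records=full)


def _iso(date_str: str, offset_days: int = 0) -> str:
    import datetime as _dt

    d = _dt.date.fromisoformat(date_str) + _dt.timedelta(days=offset_days)
    return d.isoformat()


def _study_day_date(start: str, day: int) -> str:
    # SEND day 1 is the reference start date; there is no day 0
    return _iso(start, day - 1 if day >= 1 else day)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_study(spec: StudySpec, out_dir) -> tuple[Path, GroundTruth]:
    """Write one study bundle under ``out_dir/<STUDYID>``; truth beside it."""
    spec.validate()
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    folder = out_dir / spec.studyid
    folder.mkdir(parents=True, exist_ok=True)
    sid = spec.studyid
    start = spec.start_date

    # --- subjects ------------------------------------------------------
    subjects: list[dict] = []
    control_ids: list[str] = []
    uncertain_ids: list[str] = []
    idx = 0
    for tset in spec.sets:
        for j in range(tset.n):
            idx += 1
            usubjid = f"{sid}-{idx:04d}"
            sex = "M" if j < (tset.n + 1) // 2 else "F"
            if spec.ages is not None:
                age1 = spec.ages[(idx - 1) % len(spec.ages)]
            else:
                age1 = rng.randint(*spec.age_range)
            subjects.append(
                {
                    "usubjid": usubjid,
                    "setcd": tset.setcd,
                    "tcntrl": None if spec.omit_tcntrl else tset.tcntrl,
                    "dose": tset.dose,
                    "sex": sex,
                    "age1": age1,
                }
            )
            is_control = tset.tcntrl is not None
            if is_control and not spec.omit_tcntrl:
                control_ids.append(usubjid)
            elif is_control or tset.tcntrl is None:
                uncertain_ids.append(usubjid)
    intended_controls = [
        s["usubjid"] for s in subjects
        if next(t for t in spec.sets if t.setcd == s["setcd"]).tcntrl is not None
    ]

    # --- TS -------------------------------------------------------------
    ts_params = [
        ("SDESIGN", "Study Design", spec.design),
        ("STSTDTC", "Study Start Date", start),
        ("SPECIES", "Species", spec.species),
        ("STRAIN", "Strain/Substrain", spec.strain),
        ("ROUTE", "Route of Administration", spec.route),
    ]
    ts = _domain_table(
        "TS",
        [
            {"STUDYID": sid, "TSSEQ": float(i + 1), "TSPARMCD": cd,
             "TSPARM": nm, "TSVAL": val}
            for i, (cd, nm, val) in enumerate(ts_params)
        ],
    )

    # --- TX -------------------------------------------------------------
    tx_records = []
    for tset in spec.sets:
        seq = 0
        params = []
        if tset.tcntrl is not None and not spec.omit_tcntrl:
            params.append(("TCNTRL", "Control Type", tset.tcntrl))
        else:
            params.append(
                ("TRTDOS", "Dose Level", f"{tset.dose:g}")
            )
        params.append(("SPLANSUB", "Planned Number of Subjects", str(tset.n)))
        for cd, nm, val in params:
            seq += 1
            tx_records.append(
                {"STUDYID": sid, "SETCD": tset.setcd, "SET": tset.label,
                 "TXSEQ": float(seq), "TXPARMCD": cd, "TXPARM": nm, "TXVAL": val}
            )
    tx = _domain_table("TX", tx_records)

    # --- DM -------------------------------------------------------------
    dm_records = []
    for s in subjects:
        dm_records.append(
            {
                "STUDYID": sid,
                "USUBJID": s["usubjid"],
                "SUBJID": s["usubjid"].rsplit("-", 1)[1],
                "RFSTDTC": start,
                "RFENDTC": _study_day_date(start, spec.bw_days[-1]),
                "BRTHDTC": _iso(start, -s["age1"]),
                "AGE": float(s["age1"] // 7),
                "AGEU": "WEEKS",
                "SEX": s["sex"],
                "SPECIES": "" if spec.species_in_ts_only else spec.species,
                "STRAIN": "" if spec.species_in_ts_only else spec.strain,
                "ARMCD": s["setcd"],
                "ARM": s["setcd"],
                "SETCD": s["setcd"],
            }
        )
    dm = _domain_table("DM", dm_records)

    # --- EX / DS ---------------------------------------------------------
    treatment_end = next(
        (e.end_day - 1 for e in spec.epochs if e.label == "TREATMENT" and e.end_day),
        28,
    )
    ex = _domain_table(
        "EX",
        [
            {
                "STUDYID": sid, "USUBJID": s["usubjid"], "EXSEQ": 1.0,
                "EXTRT": "VEHICLE" if s["tcntrl"] is not None or s["dose"] == 0
                else "TEST ARTICLE",
                "EXDOSE": s["dose"], "EXDOSU": "mg/kg/day",
                "EXROUTE": spec.route,
                "EXSTDTC": start,
                "EXENDTC": _study_day_date(start, treatment_end),
                "EXSTDY": 1.0, "EXENDY": float(treatment_end),
            }
            for s in subjects
        ],
    )
    last_day = spec.bw_days[-1]
    ds = _domain_table(
        "DS",
        [
            {
                "STUDYID": sid, "USUBJID": s["usubjid"], "DSSEQ": 1.0,
                "DSTERM": "TERMINAL SACRIFICE", "DSDECOD": "TERMINAL SACRIFICE",
                "DSSTDTC": _study_day_date(start, last_day),
                "DSSTDY": float(last_day),
            }
            for s in subjects
        ],
    )

    # --- SE --------------------------------------------------------------
    se_records = []
    for s in subjects:
        for k, ep in enumerate(spec.epochs):
            se_records.append(
                {
                    "STUDYID": sid, "USUBJID": s["usubjid"],
                    "SESEQ": float(k + 1), "ETCD": ep.label[:8],
                    "ELEMENT": ep.label.title(),
                    "SESTDTC": _study_day_date(start, ep.start_day),
                    "SEENDTC": "" if ep.end_day is None
                    else _study_day_date(start, ep.end_day),
                    "EPOCH": ep.label,
                }
            )
    se = _domain_table("SE", se_records)

    # --- BW / LB ---------------------------------------------------------
    bw_records, lb_records = [], []
    for s in subjects:
        for k, day in enumerate(spec.bw_days):
            value = round(rng.gauss(spec.bw_mean, spec.bw_sd) + 2.0 * k, 1)
            bw_records.append(
                {
                    "STUDYID": sid, "USUBJID": s["usubjid"],
                    "BWSEQ": float(k + 1), "BWTESTCD": "BW",
                    "BWTEST": "Body Weight",
                    "BWORRES": f"{value:g}", "BWORRESU": "g",
                    "BWSTRESC": f"{value:g}", "BWSTRESN": value, "BWSTRESU": "g",
                    "BWDTC": _study_day_date(start, day), "BWDY": float(day),
                }
            )
        seq = 0
        for plan in spec.lb_plans:
            for day in plan.days:
                seq += 1
                value = round(rng.gauss(plan.mean, plan.sd), 2)
                lb_records.append(
                    {
                        "STUDYID": sid, "USUBJID": s["usubjid"],
                        "LBSEQ": float(seq), "LBTESTCD": plan.testcd,
                        "LBTEST": plan.test, "LBCAT": "CLINICAL CHEMISTRY",
                        "LBSPEC": plan.spec,
                        "LBORRES": f"{value:g}", "LBORRESU": plan.units,
                        "LBSTRESC": f"{value:g}", "LBSTRESN": value,
                        "LBSTRESU": plan.units,
                        "LBDTC": _study_day_date(start, day), "LBDY": float(day),
                    }
                )
    bw = _domain_table("BW", bw_records)
    lb = _domain_table("LB", lb_records)

    # --- MI --------------------------------------------------------------
    not_done_ids = intended_controls[: spec.n_not_done]
    nd_specimen = spec.examined_specimens[0] if spec.examined_specimens else None
    assignable = [u for u in intended_controls if u not in not_done_ids]
    assignment: dict[tuple[str, str], str] = {}  # (usubjid, specimen) -> finding
    severity: dict[tuple[str, str], str] = {}
    mi_affected: dict[str, int] = {}
    for plan in spec.mi_plans:
        pool = [
            u for u in assignable if (u, plan.specimen) not in assignment
        ]
        chosen = rng.sample(pool, plan.n_affected)
        for u in chosen:
            assignment[(u, plan.specimen)] = plan.finding
            severity[(u, plan.specimen)] = plan.severity
        mi_affected[f"{plan.specimen}|{plan.finding}"] = plan.n_affected

    mi_records = []
    for s in subjects:
        seq = 0
        for specimen in spec.examined_specimens:
            seq += 1
            rec = {
                "STUDYID": sid, "USUBJID": s["usubjid"], "MISEQ": float(seq),
                "MITESTCD": "MIEXAM", "MITEST": "Microscopic Examination",
                "MISPEC": specimen,
                "MIDTC": _study_day_date(start, spec.mi_day),
                "MIDY": float(spec.mi_day),
            }
            if s["usubjid"] in not_done_ids and specimen == nd_specimen:
                rec.update({"MISTAT": "NOT DONE", "MIREASND": "TISSUE AUTOLYZED",
                            "MISTRESC": "", "MIDTC": "", "MIDY": None})
            else:
                finding = assignment.get((s["usubjid"], specimen))
                if finding is None:
                    rec.update({"MIORRES": "UNREMARKABLE",
                                "MISTRESC": "UNREMARKABLE"})
                else:
                    rec.update({
                        "MIORRES": finding, "MISTRESC": finding,
                        "MISEV": severity[(s["usubjid"], specimen)],
                    })
            mi_records.append(rec)
    mi = _domain_table("MI", mi_records)

    tables = {"ts": ts, "tx": tx, "dm": dm, "ex": ex, "ds": ds,
              "bw": bw, "lb": lb, "mi": mi}
    if not spec.omit_se:
        tables["se"] = se
    for stem, table in sorted(tables.items()):
        write_xpt(table, folder / f"{stem}.xpt")

    # --- ground truth ----------------------------------------------------
    from .query import classify_epoch  # local import avoids a cycle

    mi_phase = "Uncertain"
    if not spec.omit_se:
        for ep in spec.epochs:
            if ep.start_day <= spec.mi_day and (
                ep.end_day is None or spec.mi_day < ep.end_day
            ):
                mi_phase = classify_epoch(ep.label)
                break
    certain_controls = set(control_ids)
    truth = GroundTruth(
        studyid=sid,
        control_ids=sorted(control_ids),
        uncertain_ids=sorted(uncertain_ids),
        subjects={
            s["usubjid"]: {
                "setcd": s["setcd"],
                "sex": s["sex"],
                "species": spec.species,
                "strain": spec.strain,
                "route": spec.route,
                "age_at_day1": s["age1"],
                "age_at_mi": s["age1"] + spec.mi_day - 1,
                "is_control": s["usubjid"] in certain_controls,
            }
            for s in subjects
        },
        mi_affected=mi_affected,
        mi_examined={
            specimen: len(intended_controls)
            - (len(not_done_ids) if specimen == nd_specimen else 0)
            for specimen in spec.examined_specimens
        },
        mi_phase=mi_phase,
        lb={
            plan.testcd: {
                "mean": plan.mean, "sd": plan.sd, "units": plan.units,
                "n_per_control": len(plan.days),
                "n_control_records": len(plan.days) * len(intended_controls),
            }
            for plan in spec.lb_plans
        },
        n_dm_rows=len(subjects),
    )
    truth.to_json(out_dir / f"{sid}_truth.json")
    return folder, truth


def make_default_root(out_dir, base_seed: int = 0):
    """Three-study root exercising the main and the uncertain code paths.

    Study 1 (2016, PARALLEL) omits TCNTRL, study 2 (2018, PARALLEL) is fully
    featured, study 3 (2021, CROSSOVER) omits SE and keeps species/strain only
    in TS.
    """
    out_dir = Path(out_dir)
    specs = [
        StudySpec(seed=base_seed * 101 + 1, studyid="CTR2016",
                  design="PARALLEL", start_date="2016-03-01", omit_tcntrl=True),
        StudySpec(seed=base_seed * 101 + 2, studyid="CTR2018",
                  design="PARALLEL", start_date="2018-07-15"),
        StudySpec(seed=base_seed * 101 + 3, studyid="CTR2021",
                  design="CROSSOVER", start_date="2021-01-10",
                  omit_se=True, species_in_ts_only=True),
    ]
    truths = {}
    for spec in specs:
        _, truth = make_study(spec, out_dir)
        truths[spec.studyid] = truth
    return out_dir, truths


# ---------------------------------------------------------------------------
# the harmonization cohort (873 control animals)
# ---------------------------------------------------------------------------

USECASE2_TOTAL = 873
USECASE2_LUNG = (
    ("CELLULARITY, INCREASED", 6),
    ("ALVEOLAR MACROPHAGES, INCREASED", 48),
    ("AGGREGATE", 2),
)
USECASE2_SPLEEN = (
    ("CELLULARITY, INCREASED", 21),
    ("FOLLICLES, INCREASED", 3),
)


def make_usecase2_fixture(out_dir, seed: int = 0):
    """Multi-study control cohort for the harmonization worked example.

    873 control animals across three studies, each examined in both
    LUNG/BRONCHUS and SPLEEN. Lung findings: 6 CELLULARITY, INCREASED + 48
    ALVEOLAR MACROPHAGES, INCREASED + 2 AGGREGATE; spleen: 21 CELLULARITY,
    INCREASED + 3 FOLLICLES, INCREASED — one record per affected animal, all
    on distinct animals within a specimen. The seed shuffles which animals
    carry the findings; the counts are fixed.
    """
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    split = (291, 291, 291)
    assert sum(split) == USECASE2_TOTAL
    start_dates = ("2017-01-15", "2017-09-01", "2018-05-01")

    all_ids: list[tuple[str, str]] = []  # (studyid, usubjid)
    for k, n in enumerate(split):
        sid = f"HCS{k + 1:03d}"
        for i in range(n):
            all_ids.append((sid, f"{sid}-{i + 1:04d}"))

    lung_total = sum(n for _, n in USECASE2_LUNG)
    spleen_total = sum(n for _, n in USECASE2_SPLEEN)
    lung_pick = rng.sample(range(USECASE2_TOTAL), lung_total)
    spleen_pick = rng.sample(range(USECASE2_TOTAL), spleen_total)
    lung_map: dict[int, str] = {}
    pos = 0
    for finding, n in USECASE2_LUNG:
        for j in lung_pick[pos : pos + n]:
            lung_map[j] = finding
        pos += n
    spleen_map: dict[int, str] = {}
    pos = 0
    for finding, n in USECASE2_SPLEEN:
        for j in spleen_pick[pos : pos + n]:
            spleen_map[j] = finding
        pos += n

    offset = 0
    for k, n in enumerate(split):
        sid = f"HCS{k + 1:03d}"
        start = start_dates[k]
        folder = out_dir / sid
        folder.mkdir(parents=True, exist_ok=True)
        ts = _domain_table(
            "TS",
            [
                {"STUDYID": sid, "TSSEQ": float(i + 1), "TSPARMCD": cd,
                 "TSPARM": nm, "TSVAL": val}
                for i, (cd, nm, val) in enumerate(
                    [
                        ("SDESIGN", "Study Design", "PARALLEL"),
                        ("STSTDTC", "Study Start Date", start),
                        ("SPECIES", "Species", "RAT"),
                        ("STRAIN", "Strain/Substrain", "SPRAGUE-DAWLEY"),
                        ("ROUTE", "Route of Administration", "ORAL GAVAGE"),
                    ]
                )
            ],
        )
        tx = _domain_table(
            "TX",
            [
                {"STUDYID": sid, "SETCD": "CTRL", "SET": "Control",
                 "TXSEQ": 1.0, "TXPARMCD": "TCNTRL",
                 "TXPARM": "Control Type", "TXVAL": "VEHICLE CONTROL"}
            ],
        )
        dm_records, ex_records, mi_records = [], [], []
        for i in range(n):
            g = offset + i
            sid_u = all_ids[g][1]
            age1 = rng.randint(56, 120)
            dm_records.append(
                {
                    "STUDYID": sid, "USUBJID": sid_u,
                    "SUBJID": sid_u.rsplit("-", 1)[1],
                    "RFSTDTC": start, "BRTHDTC": _iso(start, -age1),
                    "AGE": float(age1 // 7), "AGEU": "WEEKS",
                    "SEX": "M" if i % 2 == 0 else "F",
                    "SPECIES": "RAT", "STRAIN": "SPRAGUE-DAWLEY",
                    "ARMCD": "CTRL", "ARM": "Control", "SETCD": "CTRL",
                }
            )
            ex_records.append(
                {
                    "STUDYID": sid, "USUBJID": sid_u, "EXSEQ": 1.0,
                    "EXTRT": "VEHICLE", "EXDOSE": 0.0, "EXDOSU": "mg/kg/day",
                    "EXROUTE": "ORAL GAVAGE", "EXSTDTC": start,
                    "EXSTDY": 1.0, "EXENDY": 28.0,
                }
            )
            for seq, (specimen, fmap) in enumerate(
                (("LUNG/BRONCHUS", lung_map), ("SPLEEN", spleen_map)), start=1
            ):
                finding = fmap.get(g)
                mi_records.append(
                    {
                        "STUDYID": sid, "USUBJID": sid_u, "MISEQ": float(seq),
                        "MITESTCD": "MIEXAM",
                        "MITEST": "Microscopic Examination",
                        "MISPEC": specimen,
                        "MIORRES": finding or "UNREMARKABLE",
                        "MISTRESC": finding or "UNREMARKABLE",
                        "MISEV": "MINIMAL" if finding else "",
                        "MIDTC": _study_day_date(start, 28), "MIDY": 28.0,
                    }
                )
        for stem, table in (
            ("ts", ts), ("tx", tx),
            ("dm", _domain_table("DM", dm_records)),
            ("ex", _domain_table("EX", ex_records)),
            ("mi", _domain_table("MI", mi_records)),
        ):
            write_xpt(table, folder / f"{stem}.xpt")
        offset += n

    truth = {
        "n_animals": USECASE2_TOTAL,
        "studies": [f"HCS{k + 1:03d}" for k in range(len(split))],
        "pre_clean": {
            "LUNG/BRONCHUS": dict(USECASE2_LUNG),
            "SPLEEN": dict(USECASE2_SPLEEN),
        },
        "post_clean": {
            "LUNG/BRONCHUS": {"CELLULARITY, INCREASED": lung_total},
            "SPLEEN": {"CELLULARITY, INCREASED": spleen_total},
        },
    }
    (out_dir / "usecase2_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out_dir, truth


# ---------------------------------------------------------------------------
# controlled-terminology fixture
# ---------------------------------------------------------------------------

_CT_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("sex", "M", "MALE;Male;m", "Yes"),
    ("sex", "F", "FEMALE;Female;f", "Yes"),
    ("sex", "U", "UNKNOWN;UNDIFFERENTIATED;Unk", "Yes"),
    ("species", "RAT", "RATS;RATTUS NORVEGICUS;Rat", "Yes"),
    ("species", "MOUSE", "MICE;MUS MUSCULUS;Mouse", "Yes"),
    ("species", "DOG", "CANINE;DOGS;BEAGLE DOG", "Yes"),
    ("strain/substrain", "SPRAGUE-DAWLEY", "SD;SPRAGUE DAWLEY;CRL:CD(SD)", "Yes"),
    ("strain/substrain", "WISTAR", "WI;HAN WISTAR;WISTAR HAN", "Yes"),
    ("strain/substrain", "BEAGLE", "PUREBRED BEAGLE;BEAGLE DOG STRAIN", "Yes"),
    ("send severity", "MINIMAL", "1;GRADE 1;SLIGHT", "Yes"),
    ("send severity", "MILD", "2;GRADE 2", "Yes"),
    ("send severity", "MODERATE", "3;GRADE 3", "Yes"),
    ("send severity", "MARKED", "4;GRADE 4", "Yes"),
    ("send severity", "SEVERE", "5;GRADE 5", "Yes"),
    ("route of administration response", "ORAL GAVAGE",
     "GAVAGE;PO GAVAGE;ORAL GAVAGE (PO)", "Yes"),
    ("route of administration response", "INTRAVENOUS", "IV;I.V.;IV BOLUS", "Yes"),
    ("route of administration response", "SUBCUTANEOUS", "SC;SUBQ;S.C.", "Yes"),
    ("standardized disposition term", "TERMINAL SACRIFICE",
     "SCHEDULED EUTHANASIA;TERMINAL KILL;SCHEDULED SACRIFICE", "Yes"),
    ("standardized disposition term", "MORIBUND SACRIFICE",
     "MORIBUND KILL;MORIBUND EUTHANASIA", "Yes"),
    ("standardized disposition term", "FOUND DEAD", "DEAD;DIED", "Yes"),
    ("specimen", "LUNG/BRONCHUS", "LUNG, BRONCHUS;LUNG WITH BRONCHI;LUNG", "Yes"),
    ("specimen", "SPLEEN", "SPLEEN, WHOLE;SPLENIC TISSUE", "Yes"),
    ("specimen", "LIVER", "HEPATIC TISSUE;LIVER, WHOLE", "Yes"),
    ("anatomical location", "ALVEOLUS", "ALVEOLI;ALVEOLAR", "Yes"),
    ("anatomical location", "CORTEX", "CORTICAL;CORTICES", "Yes"),
    ("anatomical location", "MEDULLA", "MEDULLARY;MEDULLAE", "Yes"),
    ("non-neoplastic finding type", "CELLULARITY, INCREASED",
     "ALVEOLAR MACROPHAGES, INCREASED;AGGREGATE;FOLLICLES, INCREASED;"
     "INCREASED CELLULARITY", "Yes"),
    ("non-neoplastic finding type", "NECROSIS", "NECROTIC;CELL DEATH", "Yes"),
    ("non-neoplastic finding type", "INFILTRATE",
     "INFILTRATION;CELL INFILTRATE", "Yes"),
    ("non-neoplastic finding type", "UNREMARKABLE",
     "NORMAL;WITHIN NORMAL LIMITS;NO ABNORMALITIES DETECTED", "Yes"),
    ("send control type", "VEHICLE CONTROL",
     "VEHICLE;PLACEBO CONTROL;NEGATIVE CONTROL", "Yes"),
    ("send control type", "UNTREATED CONTROL", "NO TREATMENT;UNTREATED", "Yes"),
    ("send control type", "SHAM CONTROL", "SHAM;SHAM OPERATED", "Yes"),
    ("send control type", "POSITIVE CONTROL", "ACTIVE CONTROL", "Yes"),
)


def make_ct_fixture(out_path) -> Path:
    """Write the packaged synthetic controlled-terminology file (TSV).

    Covers the ten supported codelists with >=3 preferred terms or synonyms
    each, including the extensible mappings of the harmonization worked
    example (AGGREGATE and FOLLICLES, INCREASED onto CELLULARITY, INCREASED).
    Deterministic: repeated calls are byte-identical.
    """
    out_path = Path(out_path)
    lines = ["Codelist Name\tCDISC Submission Value\tCDISC Synonym(s)\tCodelist Extensible"]
    for codelist, preferred, synonyms, ext in _CT_ROWS:
        lines.append(f"{codelist}\t{preferred}\t{synonyms}\t{ext}")
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path
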