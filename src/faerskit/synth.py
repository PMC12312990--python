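"""Synthetic FAERS quarters with known ground truth.

The generator emulates the statistical structure a disproportionality
analysis assumes: each case has one primary-suspect ingredient drawn
from a categorical exposure mix, demographics (sex, age expressed in a
mixture of FAERS age-unit codes, reporter occupation including
non-professional codes), and a set of MedDRA-style reactions drawn as
independent Bernoulli events.  Drug–event associations are injected by
odds-adjusting a reaction's background probability among cases exposed
to the signal ingredient, so that the population reporting odds ratio
against the all-other-drugs comparator equals the requested value
(optionally sex- or age-specific).

Every case additionally draws one guaranteed baseline reaction from the
*non-signal* background terms.  Real reports always list at least one
reaction; guaranteeing one avoids conditioning the retained cohort on
"at least one reaction drawn", which would otherwise tilt signal RORs
away from their injected values.  Because the guaranteed draw never
selects a signal term, injected odds ratios remain exact in the
population.

Messiness knobs — duplicate report versions, per-field missingness,
non-professional reporters, concomitant drug rows — exercise the
cleaning pipeline; the emitted manifest records the ground truth and
predicts exactly which cases survive it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .io import (
    PROFESSIONAL_OCCUPATIONS,
    RawDemoRecord,
    RawDrugRecord,
    RawReacRecord,
    write_faers_file,
)
from .preprocess import CleanCase, CleanCaseTable, Provenance, normalize_age

# years per unit, used to express a true age in the drawn unit code
_UNIT_YEARS = {"DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.1775,
               "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0}


def odds_adjust(background_p, target_ror):
    """Exposed-case reaction probability hitting a target reporting odds ratio.

    Returns ``p'`` with ``odds(p')/odds(background_p) == target_ror``:
    ``p' = ror*o / (1 + ror*o)`` where ``o`` is the background odds.
    Accepts scalars or numpy arrays; ``background_p`` must be strictly
    inside (0, 1) and ``target_ror`` strictly positive.
    """
    p = np.asarray(background_p, dtype=float)
    r = np.asarray(target_ror, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("background_p must lie strictly between 0 and 1")
    if np.any(r <= 0.0):
        raise ValueError("target_ror must be positive")
    ro = r * (p / (1.0 - p))
    out = ro / (1.0 + ro)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Signal:
    """An injected drug–event association with optional subgroup structure."""

    ingredient: str
    pt: str
    ror: float
    sex_ror: Optional[Mapping[str, float]] = None  # keys: female, male
    age_ror: Optional[Mapping[str, float]] = None  # keys: older, younger

    def __post_init__(self):
        if self.ror <= 0:
            raise ValueError("signal ror must be positive")


_DEFAULT_INGREDIENTS = (
    ("DRUG_A", 0.12),
    ("DRUG_B", 0.12),
    ("DRUG_C", 0.16),
    ("DRUG_D", 0.20),
    ("DRUG_E", 0.18),
    ("DRUG_F", 0.22),
)

_DEFAULT_PTS = (
    ("Nausea", 0.12),
    ("Headache", 0.10),
    ("Diarrhoea", 0.08),
    ("Dizziness", 0.07),
    ("Vomiting", 0.07),
    ("Rash", 0.06),
    ("Fatigue", 0.06),
    ("Pruritus", 0.05),
    ("Dysgeusia", 0.04),
    ("Alopecia", 0.03),
    ("Retinopathy", 0.02),
    ("Cardiomyopathy", 0.015),
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic quarter.

    Defaults model a professional-dominated spontaneous-report stream:
    a female-skewed sex mix, ages centred near 58 years expressed mostly
    in years but also in the other FAERS unit codes, ~8% consumer
    reports, 5% resubmitted case versions and realistic per-field
    missingness.
    """

    n_cases: int = 10_000
    ingredients: Tuple[Tuple[str, float], ...] = _DEFAULT_INGREDIENTS
    pts: Tuple[Tuple[str, float], ...] = _DEFAULT_PTS
    signals: Tuple[Signal, ...] = ()
    sex_probs: Tuple[Tuple[str, float], ...] = (("F", 0.55), ("M", 0.40), ("UNK", 0.05))
    age_mean: float = 58.0
    age_sd: float = 18.0
    age_unit_probs: Tuple[Tuple[str, float], ...] = (
        ("YR", 0.86), ("DEC", 0.02), ("MON", 0.05), ("WK", 0.02), ("DY", 0.04), ("HR", 0.01)
    )
    occupation_probs: Tuple[Tuple[str, float], ...] = (
        ("MD", 0.38), ("PH", 0.22), ("OT", 0.18), ("HP", 0.12), ("CN", 0.08), ("", 0.02)
    )
    duplicate_version_rate: float = 0.05
    missing_age_rate: float = 0.12
    missing_sex_rate: float = 0.05
    missing_prod_ai_rate: float = 0.01
    concomitant_rate: float = 0.30
    age_split: float = 50.0
    quarter: str = "2023Q1"
    caseid_start: int = 10_000_000  # distinct ranges keep multi-quarter caseids unique
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name, rate in [
            ("duplicate_version_rate", self.duplicate_version_rate),
            ("missing_age_rate", self.missing_age_rate),
            ("missing_sex_rate", self.missing_sex_rate),
            ("missing_prod_ai_rate", self.missing_prod_ai_rate),
            ("concomitant_rate", self.concomitant_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        known_pts = {pt for pt, _ in self.pts}
        known_ing = {name for name, _ in self.ingredients}
        for sig in self.signals:
            if sig.pt not in known_pts:
                raise ValueError(f"signal pt {sig.pt!r} not in the pts list")
            if sig.ingredient not in known_ing:
                raise ValueError(f"signal ingredient {sig.ingredient!r} not in the ingredients list")

    # -- plain-text config round-trip (YAML) --

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signals"] = [
            {k: v for k, v in dataclasses.asdict(s).items() if v is not None}
            for s in self.signals
        ]
        for key in ("ingredients", "pts", "sex_probs", "age_unit_probs", "occupation_probs"):
            d[key] = [list(pair) for pair in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "signals" in d:
            d["signals"] = tuple(
                s if isinstance(s, Signal) else Signal(**s) for s in d["signals"]
            )
        for key in ("ingredients", "pts", "sex_probs", "age_unit_probs", "occupation_probs"):
            if key in d:
                d[key] = tuple((str(name), float(p)) for name, p in d[key])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _choice(rng, options: Sequence[str], probs: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("probabilities must not all be zero")
    return rng.choice(np.asarray(options, dtype=object), size=n, p=p / total)


def _draw_arrays(config: SynthConfig) -> dict:
    """Vectorized ground-truth draws shared by all generator entry points.

    The RNG call order is fixed, so every consumer of a given config sees
    the same population.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    ing_names = [name for name, _ in config.ingredients]
    ing_idx = (
        _choice(rng, [str(i) for i in range(len(ing_names))],
                [p for _, p in config.ingredients], n).astype(int)
        if n else np.array([], dtype=int)
    )
    sex = _choice(rng, [s for s, _ in config.sex_probs], [p for _, p in config.sex_probs], n)
    age_true = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.5, 100.0)

    pt_names = [pt for pt, _ in config.pts]
    pt_bg = np.array([p for _, p in config.pts])
    signal_pt_idx = {pt_names.index(s.pt) for s in config.signals}
    member = np.zeros((n, len(pt_names)), dtype=bool)
    older = age_true > config.age_split
    for j, pt in enumerate(pt_names):
        p_vec = np.full(n, pt_bg[j])
        for sig in config.signals:
            if sig.pt != pt:
                continue
            mask = ing_idx == ing_names.index(sig.ingredient)
            ror_case = np.full(n, sig.ror)
            if sig.sex_ror:
                if "female" in sig.sex_ror:
                    ror_case[sex == "F"] = sig.sex_ror["female"]
                if "male" in sig.sex_ror:
                    ror_case[sex == "M"] = sig.sex_ror["male"]
            if sig.age_ror:
                if "older" in sig.age_ror:
                    ror_case[older] = sig.age_ror["older"]
                if "younger" in sig.age_ror:
                    ror_case[~older] = sig.age_ror["younger"]
            if mask.any():
                p_vec[mask] = odds_adjust(pt_bg[j], ror_case[mask])
        member[:, j] = rng.random(n) < p_vec

    nonsig = [j for j in range(len(pt_names)) if j not in signal_pt_idx]
    if nonsig and n:
        w = pt_bg[nonsig] / pt_bg[nonsig].sum()
        guaranteed = rng.choice(np.asarray(nonsig), size=n, p=w)
        member[np.arange(n), guaranteed] = True

    occp = _choice(rng, [o for o, _ in config.occupation_probs],
                   [p for _, p in config.occupation_probs], n)
    unit = _choice(rng, [u for u, _ in config.age_unit_probs],
                   [p for _, p in config.age_unit_probs], n)
    age_missing = rng.random(n) < config.missing_age_rate
    sex_missing = rng.random(n) < config.missing_sex_rate
    ai_missing = rng.random(n) < config.missing_prod_ai_rate
    duplicate = rng.random(n) < config.duplicate_version_rate
    degrade = _choice(rng, ["sex", "age"], [0.5, 0.5], n)
    concomitant = rng.random(n) < config.concomitant_rate
    conc_idx = (
        _choice(rng, [str(i) for i in range(len(ing_names))],
                [p for _, p in config.ingredients], n).astype(int)
        if n else np.array([], dtype=int)
    )

    unit_factor = np.array([_UNIT_YEARS[u] for u in unit]) if n else np.array([])
    reported_age = np.round(age_true / unit_factor, 2) if n else np.array([])

    professional = np.array(
        [str(o).upper() in PROFESSIONAL_OCCUPATIONS for o in occp], dtype=bool
    )
    has_pts = member.any(axis=1) if n else np.array([], dtype=bool)
    essentials = ~ai_missing & has_pts

    return {
        "ing_names": ing_names, "pt_names": pt_names, "ing_idx": ing_idx,
        "sex": sex, "age_true": age_true, "member": member, "occp": occp,
        "unit": unit, "reported_age": reported_age, "age_missing": age_missing,
        "sex_missing": sex_missing, "ai_missing": ai_missing,
        "duplicate": duplicate, "degrade": degrade,
        "concomitant": concomitant, "conc_idx": conc_idx,
        "professional": professional, "essentials": essentials,
        "retained": professional & essentials,
    }


def simulate_truth(config: SynthConfig) -> pd.DataFrame:
    """Draw the ground truth for every case (pre-missingness).

    One row per case: identifiers, true ingredient, demographics, the
    reaction set, messiness flags, and the survival prediction
    (``expected_retained`` / ``drop_stage``) for the cleaning pipeline.
    """
    arr = _draw_arrays(config)
    n = config.n_cases
    ing_names, pt_names = arr["ing_names"], arr["pt_names"]
    member = arr["member"]

    pt_lists: List[List[str]] = [[] for _ in range(n)]
    for j, name in enumerate(pt_names):
        for i in np.flatnonzero(member[:, j]):
            pt_lists[i].append(name)
    pts_joined = ["|".join(sorted(lst)) for lst in pt_lists]

    caseids = [str(config.caseid_start + i) for i in range(n)]
    versions = np.where(arr["duplicate"], 2, 1)

    drop_stage = np.full(n, "", dtype=object)
    drop_stage[~arr["professional"]] = "nonprofessional"
    drop_stage[arr["professional"] & ~arr["essentials"]] = "missing_essentials"

    return pd.DataFrame(
        {
            "caseid": caseids,
            "final_primaryid": [f"{cid}{v}" for cid, v in zip(caseids, versions)],
            "ingredient": [ing_names[i] for i in arr["ing_idx"]],
            "pts": pts_joined,
            "sex_true": arr["sex"],
            "age_years_true": arr["age_true"],
            "age_reported": arr["reported_age"],
            "age_unit": arr["unit"],
            "occp_cod": arr["occp"],
            "n_versions": versions,
            "age_missing": arr["age_missing"],
            "sex_missing": arr["sex_missing"],
            "ai_missing": arr["ai_missing"],
            "degrade_field": arr["degrade"],
            "concomitant": [
                ing_names[i] if c else ""
                for i, c in zip(arr["conc_idx"], arr["concomitant"])
            ],
            "expected_retained": arr["retained"],
            "drop_stage": drop_stage,
        }
    )


def signal_contingency(config: SynthConfig, ingredient: str, pt: str,
                       stratum: Optional[str] = None):
    """Contingency table for one drug–reaction pair among retained cases.

    Vectorized fast path for simulation studies: counts exposure x event
    over the cases the cleaning pipeline would retain, without
    materializing files or case objects.  ``stratum`` restricts the
    cohort to ``"female"``/``"male"`` (true sex) or ``"older"``/
    ``"younger"`` (true age vs ``config.age_split``).  Identical draws to
    :func:`simulate_truth` for the same config.
    """
    from .stats import ContingencyTable

    arr = _draw_arrays(config)
    keep = arr["retained"].copy()
    if stratum is not None:
        if stratum == "female":
            keep &= ~arr["sex_missing"] & (arr["sex"] == "F")
        elif stratum == "male":
            keep &= ~arr["sex_missing"] & (arr["sex"] == "M")
        elif stratum == "older":
            keep &= ~arr["age_missing"] & (arr["age_true"] > config.age_split)
        elif stratum == "younger":
            keep &= ~arr["age_missing"] & (arr["age_true"] <= config.age_split)
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
    exposed = arr["ing_idx"] == arr["ing_names"].index(ingredient)
    event = arr["member"][:, arr["pt_names"].index(pt)]
    a = int(np.sum(keep & exposed & event))
    b = int(np.sum(keep & exposed & ~event))
    c = int(np.sum(keep & ~exposed & event))
    d = int(np.sum(keep & ~exposed & ~event))
    return ContingencyTable(a, b, c, d)


def _truth_to_records(truth: pd.DataFrame, quarter: str):
    demo: List[RawDemoRecord] = []
    drug: List[RawDrugRecord] = []
    reac: List[RawReacRecord] = []
    for row in truth.itertuples(index=False):
        final_sex = None if row.sex_missing else str(row.sex_true)
        final_age = None if row.age_missing else float(row.age_reported)
        final_cod = None if row.age_missing else str(row.age_unit)
        occp = str(row.occp_cod) or None
        pts = [p for p in str(row.pts).split("|") if p]
        prod_ai = None if row.ai_missing else str(row.ingredient)

        version_rows = []
        if row.n_versions > 1:
            sup_sex, sup_age, sup_cod = final_sex, final_age, final_cod
            if row.degrade_field == "sex":
                sup_sex = None
            else:
                sup_age, sup_cod = None, None
            version_rows.append((1, sup_sex, sup_age, sup_cod))
        version_rows.append((int(row.n_versions), final_sex, final_age, final_cod))

        for version, v_sex, v_age, v_cod in version_rows:
            pid = f"{row.caseid}{version}"
            demo.append(
                RawDemoRecord(
                    primaryid=pid, caseid=str(row.caseid), caseversion=version,
                    age=v_age, age_cod=v_cod, sex=v_sex, occp_cod=occp, quarter=quarter,
                )
            )
            drug.append(
                RawDrugRecord(primaryid=pid, drug_seq=1, role_cod="PS",
                              prod_ai=prod_ai, drugname=prod_ai)
            )
            if row.concomitant:
                drug.append(
                    RawDrugRecord(primaryid=pid, drug_seq=2, role_cod="C",
                                  prod_ai=str(row.concomitant), drugname=str(row.concomitant))
                )
            for pt in pts:
                reac.append(RawReacRecord(primaryid=pid, pt=pt))
    return demo, drug, reac


@dataclass
class GeneratedQuarter:
    """Paths and ground truth of one generated quarter."""

    demo_path: Path
    drug_path: Path
    reac_path: Path
    manifest_path: Path
    manifest: pd.DataFrame
    config: SynthConfig


def generate_quarter(config: SynthConfig, out_dir: Union[str, Path]) -> GeneratedQuarter:
    """Write a DEMO/DRUG/REAC trio plus a ground-truth manifest.

    File names follow the FAERS convention (e.g. ``DEMO23Q1.txt`` for
    quarter 2023Q1).  Same config (including seed) gives byte-identical
    output.  With ``n_cases == 0`` the three files contain only their
    header lines and the manifest is empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    demo, drug, reac = _truth_to_records(truth, config.quarter)

    yy, q = config.quarter[2:4], config.quarter[4:6]
    paths = {kind: out_dir / f"{kind.upper()}{yy}{q}.txt" for kind in ("demo", "drug", "reac")}
    write_faers_file(demo, paths["demo"])
    write_faers_file(drug, paths["drug"])
    write_faers_file(reac, paths["reac"])
    manifest_path = out_dir / f"manifest{yy}{q}.tsv"
    truth.to_csv(manifest_path, sep="\t", index=False, float_format="%.6f")
    return GeneratedQuarter(
        demo_path=paths["demo"], drug_path=paths["drug"], reac_path=paths["reac"],
        manifest_path=manifest_path, manifest=truth, config=config,
    )


def simulate_case_table(config: SynthConfig) -> CleanCaseTable:
    """The clean case table the full pipeline would produce, built directly.

    Skips file round-tripping: applies the survival prediction of
    :func:`simulate_truth` and assembles :class:`CleanCase` rows for the
    retained cases.  Matches ``preprocess_quarters`` applied to the
    written files record-for-record (tested), and is the fast path for
    large simulation studies.
    """
    truth = simulate_truth(config)
    cases = []
    prov = Provenance(
        quarters=(config.quarter,),
        raw_demo_rows=int(truth["n_versions"].sum()) if len(truth) else 0,
    )
    for row in truth.itertuples(index=False):
        if row.drop_stage == "nonprofessional":
            prov.dropped_nonprofessional += int(row.n_versions)
            continue
        prov.dropped_duplicate_version += int(row.n_versions) - 1
        if row.drop_stage == "missing_essentials":
            prov.dropped_missing_essentials += 1
            continue
        sex = "unknown" if row.sex_missing else {"F": "female", "M": "male"}.get(str(row.sex_true), "unknown")
        age_years = None if row.age_missing else normalize_age(float(row.age_reported), str(row.age_unit))
        cases.append(
            CleanCase(
                caseid=str(row.caseid),
                primaryid=str(row.final_primaryid),
                sex=sex,
                age_years=age_years,
                reporter=str(row.occp_cod) or None,
                ps_ingredients=frozenset({str(row.ingredient)}),
                pts=frozenset(p for p in str(row.pts).split("|") if p),
            )
        )
    prov.retained = len(cases)
    return CleanCaseTable(cases, prov)
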