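"""Annotation engine: m/z database matching, CCS-based candidate filtering,
isobar adjudication and sum-composition consistency checks.

The central idea: a measured CCS, when accurate to well under 1%, can
adjudicate between database entries or structure candidates that are
indistinguishable by MS1 m/z alone.  Candidates whose predicted CCS differs
from the experimental CCS by more than a threshold (default +-1%) are
discarded; among surviving isobars the smallest |percent difference| wins,
with near-ties flagged as genuinely ambiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import pandas as pd

from .masscalc import ADDUCTS, ElementalFormula, adduct_mz, monoisotopic_mass, ppm_error
from .predictor import percent_difference

__all__ = [
    "DatabaseEntry",
    "load_database",
    "Match",
    "db_match",
    "Candidate",
    "FilterResult",
    "filter_candidates",
    "Adjudication",
    "adjudicate_isobars",
    "sum_composition_check",
    "ingest_candidates",
    "AnnotationReport",
    "annotate_feature",
]

DEFAULT_ADDUCTS: Tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+", "[M+2H]2+")


@dataclass(frozen=True)
class DatabaseEntry:
    """One neutral compound in a local annotation database."""

    name: str
    formula: ElementalFormula
    mass: float  # neutral monoisotopic mass, Da
    class_tag: str = ""  # e.g. lipid sum-composition label such as "PE(34:1)"

    @classmethod
    def from_formula(
        cls, name: str, formula: Union[str, ElementalFormula], class_tag: str = ""
    ) -> "DatabaseEntry":
        if not isinstance(formula, ElementalFormula):
            formula = ElementalFormula(formula)
        return cls(name=name, formula=formula, mass=monoisotopic_mass(formula), class_tag=class_tag)


def load_database(source: Union[str, pd.DataFrame]) -> List[DatabaseEntry]:
    """Load a delimited database (columns: name, formula[, mass, class]).

    When a mass column is present it is checked against the formula mass
    (1 mDa tolerance); otherwise the mass is computed from the formula.
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ValueError(f"database is missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        formula = ElementalFormula(str(row["formula"]))
        mass = monoisotopic_mass(formula)
        if "mass" in df.columns and pd.notna(row["mass"]):
            if abs(float(row["mass"]) - mass) > 1e-3:
                raise ValueError(
                    f"entry {row['name']!r}: stated mass {row['mass']} "
                    f"disagrees with formula mass {mass:.5f}"
                )
        entries.append(
            DatabaseEntry(
                name=str(row["name"]),
                formula=formula,
                mass=mass,
                class_tag=str(row["class"]) if "class" in df.columns and pd.notna(row.get("class")) else "",
            )
        )
    if not entries:
        raise ValueError("database is empty")
    return entries


@dataclass(frozen=True)
class Match:
    """A database entry matching a query m/z under one adduct."""

    entry: DatabaseEntry
    adduct: str
    theoretical_mz: float
    error: float  # in the units of tol_mode (Da or ppm)
    tol_mode: str


def db_match(
    mz: float,
    database: Sequence[DatabaseEntry],
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    tol: float = 5.0,
    tol_mode: str = "ppm",
) -> List[Match]:
    """All (entry, adduct) combinations whose theoretical m/z lies within
    tolerance of the query (inclusive bounds), sorted by |error|.

    ``tol_mode`` selects absolute-Da or ppm tolerance, mirroring the two
    conventions of common lipid and metabolite databases.
    """
    if not database:
        raise ValueError("database is empty")
    if tol_mode not in ("ppm", "da"):
        raise ValueError("tol_mode must be 'ppm' or 'da'")
    out = []
    for entry in database:
        for adduct in adducts:
            if adduct not in ADDUCTS:
                raise ValueError(f"unsupported adduct {adduct!r}")
            theo = adduct_mz(entry.mass, adduct)
            err = ppm_error(mz, theo) if tol_mode == "ppm" else mz - theo
            if abs(err) <= tol:
                out.append(
                    Match(entry=entry, adduct=adduct, theoretical_mz=theo,
                          error=err, tol_mode=tol_mode)
                )
    out.sort(key=lambda m: (abs(m.error), m.entry.name, m.adduct))
    return out


@dataclass
class Candidate:
    """A proposed structure for a feature, with its CCS-based evidence."""

    rank: int
    structure: str  # SMILES
    formula: Union[str, ElementalFormula]
    adduct: str
    source: str = "database"  # "database" | "de novo"
    predicted_ccs: Optional[float] = None
    percent_diff: Optional[float] = None  # signed %, predicted vs experimental
    sum_match: Optional[bool] = None
    disposition: Optional[str] = None  # "kept" | "removed"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.source not in ("database", "de novo"):
            raise ValueError(f"unknown candidate source {self.source!r}")


@dataclass(frozen=True)
class FilterResult:
    kept: List[Candidate]
    removed: List[Candidate]

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.removed)


def filter_candidates(
    candidates: Sequence[Candidate], threshold_pct: float = 1.0
) -> FilterResult:
    """Partition candidates by |percent CCS difference| vs a threshold.

    Removed: |percent_diff| strictly greater than ``threshold_pct``; kept is
    the complement (boundary values survive, consistent with inclusive "+-"
    tolerances).  Dispositions are set on the candidates.
    """
    kept: List[Candidate] = []
    removed: List[Candidate] = []
    for c in candidates:
        if c.percent_diff is None:
            raise ValueError(f"candidate rank {c.rank} has no percent difference")
        if abs(c.percent_diff) > threshold_pct:
            c.disposition = "removed"
            removed.append(c)
        else:
            c.disposition = "kept"
            kept.append(c)
    return FilterResult(kept=kept, removed=removed)


@dataclass(frozen=True)
class Adjudication:
    ranked: List[Candidate]  # by ascending |percent diff|
    winner: Optional[Candidate]
    ambiguous: bool


def adjudicate_isobars(
    experimental_ccs: float,
    candidates: Sequence[Candidate],
    tie_window_pct: float = 0.05,
) -> Adjudication:
    """Rank isobaric candidates by |percent CCS difference|; smallest wins.

    Percent differences are (re)computed from ``predicted_ccs`` when
    available.  If the two best candidates are within ``tie_window_pct``
    percentage points of each other the call is flagged ambiguous and no
    winner is returned: the tie window sits below the method's demonstrated
    accuracy, so such ties are genuinely unresolvable.
    """
    if len(candidates) < 2:
        raise ValueError("isobar adjudication needs at least 2 candidates")
    for c in candidates:
        if c.predicted_ccs is not None:
            c.percent_diff = percent_difference(c.predicted_ccs, experimental_ccs)
        if c.percent_diff is None:
            raise ValueError(f"candidate rank {c.rank} has no CCS prediction")
    ranked = sorted(candidates, key=lambda c: (abs(c.percent_diff), c.rank))
    gap = abs(abs(ranked[0].percent_diff) - abs(ranked[1].percent_diff))
    if gap <= tie_window_pct:
        return Adjudication(ranked=ranked, winner=None, ambiguous=True)
    return Adjudication(ranked=ranked, winner=ranked[0], ambiguous=False)


def sum_composition_check(
    candidate: Candidate, putative: Tuple[DatabaseEntry, str]
) -> bool:
    """True iff the candidate's elemental formula and adduct both equal the
    putative database annotation's.

    Formula + adduct equality is a robust, format-free proxy for lipid
    sum-composition agreement (same class, total carbons and double-bond
    count imply the same formula); a candidate predicted as a different
    adduct of the same formula fails the check.
    """
    entry, adduct = putative
    cf = candidate.formula
    if not isinstance(cf, ElementalFormula):
        cf = ElementalFormula(str(cf))
    return cf == entry.formula and candidate.adduct == adduct


def ingest_candidates(
    source: Union[str, pd.DataFrame], top_k: Optional[int] = 20
) -> List[Candidate]:
    """Read a structure-candidate export (SIRIUS-style delimited file).

    Required columns: rank, structure, formula, adduct, source; optional:
    predicted_ccs.  Ranks must be unique; rows with unparseable structures
    are skipped with a warning; the list is rank-ordered and truncated to
    ``top_k`` (None keeps all).
    """
    from rdkit import Chem, RDLogger

    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    required = ("rank", "structure", "formula", "adduct", "source")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"candidate file is missing column {col!r}")
    ranks = df["rank"].tolist()
    if len(ranks) != len(set(ranks)):
        raise ValueError("duplicate ranks in candidate file")

    RDLogger.DisableLog("rdApp.error")
    try:
        out = []
        for _, row in df.sort_values("rank").iterrows():
            smiles = str(row["structure"])
            if Chem.MolFromSmiles(smiles) is None:
                warnings.warn(
                    f"skipping rank {row['rank']}: unparseable structure {smiles!r}",
                    stacklevel=2,
                )
                continue
            out.append(
                Candidate(
                    rank=int(row["rank"]),
                    structure=smiles,
                    formula=str(row["formula"]),
                    adduct=str(row["adduct"]),
                    source=str(row["source"]),
                    predicted_ccs=(
                        float(row["predicted_ccs"])
                        if "predicted_ccs" in df.columns and pd.notna(row["predicted_ccs"])
                        else None
                    ),
                )
            )
    finally:
        RDLogger.EnableLog("rdApp.error")
    return out[:top_k] if top_k is not None else out


@dataclass
class AnnotationReport:
    """Everything the workflow concluded about one feature."""

    feature_mz: float
    experimental_ccs: Optional[float]
    matches: List[Match] = field(default_factory=list)
    candidates: List[Candidate] = field(default_factory=list)
    kept: List[Candidate] = field(default_factory=list)
    removed: List[Candidate] = field(default_factory=list)
    winner: Optional[Candidate] = None
    ambiguous: bool = False
    status: str = "unknown"  # "annotated" | "ambiguous" | "unknown"

    @property
    def n_total(self) -> int:
        return len(self.candidates)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def summary(self) -> dict:
        return {
            "feature_mz": self.feature_mz,
            "experimental_ccs": self.experimental_ccs,
            "n_db_matches": len(self.matches),
            "n_candidates": self.n_total,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "winner": self.winner.structure if self.winner else None,
            "ambiguous": self.ambiguous,
            "status": self.status,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def annotate_feature(
    feature_mz: float,
    experimental_ccs: Optional[float],
    database: Sequence[DatabaseEntry],
    candidates: Sequence[Candidate],
    predictor=None,
    *,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    db_tol: float = 5.0,
    db_tol_mode: str = "ppm",
    ccs_threshold_pct: float = 1.0,
    tie_window_pct: float = 0.05,
) -> AnnotationReport:
    """Full annotation of one feature: database match -> CCS prediction ->
    percent difference -> threshold filter -> isobar adjudication ->
    sum-composition check.

    ``predictor`` is any ``(structure, adduct) -> CCS`` callable (for
    example a dict of trained :class:`~cimccs.predictor.PredictorModel`
    objects wrapped by :func:`~cimccs.predictor.predict_with_fallback`);
    candidates that already carry ``predicted_ccs`` skip it.
    """
    report = AnnotationReport(feature_mz=feature_mz, experimental_ccs=experimental_ccs)
    report.candidates = list(candidates)
    if database:
        report.matches = db_match(
            feature_mz, database, adducts=adducts, tol=db_tol, tol_mode=db_tol_mode
        )

    if experimental_ccs is not None and report.candidates:
        for c in report.candidates:
            if c.predicted_ccs is None and predictor is not None:
                c.predicted_ccs = float(predictor(c.structure, c.adduct))
            if c.predicted_ccs is not None:
                c.percent_diff = percent_difference(c.predicted_ccs, experimental_ccs)
        scored = [c for c in report.candidates if c.percent_diff is not None]
        if report.matches:
            top = report.matches[0]
            for c in scored:
                c.sum_match = sum_composition_check(c, (top.entry, top.adduct))
        if scored:
            result = filter_candidates(scored, threshold_pct=ccs_threshold_pct)
            report.kept, report.removed = result.kept, result.removed
            if len(report.kept) >= 2:
                adj = adjudicate_isobars(
                    experimental_ccs, report.kept, tie_window_pct=tie_window_pct
                )
                report.winner, report.ambiguous = adj.winner, adj.ambiguous
            elif len(report.kept) == 1:
                report.winner = report.kept[0]

    if report.winner is not None:
        report.status = "annotated"
    elif report.ambiguous:
        report.status = "ambiguous"
    elif report.matches and not report.candidates:
        report.status = "putative"
    else:
        report.status = "unknown"
    return report
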