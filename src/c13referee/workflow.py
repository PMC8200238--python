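"""The full referee workflow and report rendering.

Runs the complete twelve-step pipeline on one submission (an SDF of
structure proposals plus their peak lists against a reference database):

1. formal structure check, 2. identifier table, 3. peak-list check,
4. environment-code shift prediction, 5. prediction statistics,
6. signal assignment, 7. coincidence report, 8. identical-structure search,
9. identical-pattern search, 10. large-deviation detection, 11. structure
generation and ranking, 12. peak-list dereplication — and emits one
machine-readable (JSON) and one human-readable (text/HTML) protocol per
compound, suitable for attaching to a manuscript.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import similarity
from .chem_core import (
    Molecule,
    canonical_identifier,
    check_structure,
    molecular_weight,
)
from .hose import (
    DEFAULT_MAX_SPHERE,
    DEFAULT_MIN_CONTRIBUTORS,
    HoseIndex,
    ReferenceRecord,
    build_index,
    predict_shifts,
)
from .revision import flag_positions, generate_candidates, rank_candidates
from .verification import (
    ClassificationThresholds,
    PeakList,
    VerificationReport,
    verify,
)

logger = logging.getLogger("c13referee")

__all__ = ["WorkflowConfig", "CompoundReport", "run_workflow", "render_report"]

DISPLAY_CAP = 99.0  # deviations larger than 99 ppm are always shown as 99


@dataclass
class WorkflowConfig:
    max_sphere: int = DEFAULT_MAX_SPHERE
    min_contributors: int = DEFAULT_MIN_CONTRIBUTORS
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    pattern_tolerance: float = similarity.DEFAULT_PATTERN_TOLERANCE
    flag_level: str = "red"
    revision_budget: int = 5000
    revision_top: int = 20
    dereplication_top: int = 10
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "WorkflowConfig":
        thresholds = ClassificationThresholds(
            green_below=data.get("green_below", 5.0),
            red_above=data.get("red_above", 10.0),
            gross_error=data.get("gross_error", 20.0),
        )
        return cls(
            max_sphere=data.get("max_sphere", DEFAULT_MAX_SPHERE),
            min_contributors=data.get("min_contributors", DEFAULT_MIN_CONTRIBUTORS),
            thresholds=thresholds,
            pattern_tolerance=data.get(
                "pattern_tolerance", similarity.DEFAULT_PATTERN_TOLERANCE
            ),
            flag_level=data.get("flag_level", "red"),
            revision_budget=data.get("revision_budget", 5000),
            revision_top=data.get("revision_top", 20),
            dereplication_top=data.get("dereplication_top", 10),
            seed=data.get("seed", 0),
        )


@dataclass
class CompoundReport:
    name: str
    identifier: str
    formula_weight: float
    verification: VerificationReport
    identical_structures: list[int]
    pattern_matches: list[similarity.PatternMatch]
    flagged_atoms: list[int]
    revision_rank: Optional[int]
    revision_recommended: bool
    revision_table: list[dict]
    dereplication: list[dict]
    verdict: str = ""  # "consistent" | "warnings" | "inconsistent"

    def to_json_dict(self) -> dict:
        v = self.verification
        return {
            "compound": self.name,
            "identifier": self.identifier,
            "molecular_weight_amu": round(self.formula_weight, 2),
            "verdict": self.verdict,
            "status": v.status,
            "assignment_mode": v.assignment_mode,
            "delta_mean_ppm": None if v.delta_mean is None else round(v.delta_mean, 3),
            "delta_max_ppm": None if v.delta_max is None else round(v.delta_max, 3),
            "gross_error": v.gross_error,
            "color_counts": v.color_counts(),
            "findings": [
                {
                    "severity": f.severity,
                    "code": f.code,
                    "message": f.message,
                    "atoms": list(f.atoms),
                }
                for f in v.findings
            ],
            "deviations": [
                {
                    "class": d.class_id,
                    "atoms": list(d.atoms),
                    "experimental_ppm": d.experimental,
                    "predicted_ppm": None if d.predicted is None else round(d.predicted, 2),
                    "delta_ppm": None if d.delta is None else round(d.delta, 2),
                    "color": d.color,
                    "n": d.n,
                    "std_ppm": round(d.std, 2),
                    "sphere": d.sphere,
                    "provenance": d.provenance,
                }
                for d in v.deviations
            ],
            "identical_structures": self.identical_structures,
            "pattern_matches": [
                {
                    "record": pm.record_id,
                    "max_difference_ppm": round(pm.max_difference, 3),
                    "same_data_different_structure": pm.same_data_different_structure,
                }
                for pm in self.pattern_matches
            ],
            "flagged_atoms": self.flagged_atoms,
            "revision": {
                "input_rank": self.revision_rank,
                "recommended": self.revision_recommended,
                "table": self.revision_table,
            },
            "dereplication": self.dereplication,
        }


def _verdict(report: CompoundReport) -> str:
    v = report.verification
    if (
        v.status != "ok"
        or v.gross_error
        or any(f.severity == "error" for f in v.findings)
        or report.revision_recommended
        or any(pm.same_data_different_structure for pm in report.pattern_matches)
    ):
        return "inconsistent"
    counts = v.color_counts()
    if counts["yellow"] or counts["red"] or any(
        f.severity == "warning" for f in v.findings
    ):
        return "warnings"
    return "consistent"


def run_workflow(
    compounds: Sequence[tuple[Molecule, PeakList]],
    db: Sequence[ReferenceRecord],
    config: Optional[WorkflowConfig] = None,
    index: Optional[HoseIndex] = None,
) -> list[CompoundReport]:
    """Run the twelve-step referee workflow on every submitted compound."""
    cfg = config or WorkflowConfig()
    t0 = time.time()
    if index is None:
        index = build_index(db, max_sphere=cfg.max_sphere)
    logger.info(
        "workflow: %d compounds, %d reference records, config=%s",
        len(compounds), len(db), cfg,
    )

    # step-12 backdrop: predicted spectra of the reference structures
    predicted_spectra = []
    for rid, rec in enumerate(db):
        preds = predict_shifts(rec.molecule, index, cfg.min_contributors)
        shifts = [pr.shift for pr in preds if pr.predicted]
        predicted_spectra.append((rec.name or f"record-{rid}", shifts))

    reports: list[CompoundReport] = []
    for m, p in compounds:
        name = m.name or p.key or f"compound-{len(reports) + 1}"
        structure_check = check_structure(m)  # step 1
        if structure_check.ok:
            ident = canonical_identifier(m).text  # step 2
            mw = molecular_weight(m)
        else:
            ident = ""
            mw = 0.0
        # steps 3-7
        report = verify(
            m, p, index,
            thresholds=cfg.thresholds,
            min_contributors=cfg.min_contributors,
        )
        if structure_check.ok:
            identical = similarity.find_identical_structures(m, db)  # step 8
            patterns = similarity.find_identical_patterns(  # step 9
                p, db, tolerance=cfg.pattern_tolerance, query_structure=m
            )
        else:
            identical, patterns = [], []

        flagged: list[int] = []
        rank = None
        recommended = False
        table: list[dict] = []
        if report.status == "ok":
            flagged = sorted(
                flag_positions(report, level=cfg.flag_level, molecule=m)  # step 10
            )
            if flagged:
                candidates, truncated = generate_candidates(  # step 11
                    m, flagged, budget=cfg.revision_budget
                )
                ranked = rank_candidates(
                    candidates, p, index,
                    min_contributors=cfg.min_contributors,
                    truncated=truncated,
                )
                rank = ranked.input_rank
                recommended = ranked.revision_recommended
                table = [
                    {
                        "rank": c.rank,
                        "identifier": c.identifier,
                        "score_ppm": None if c.score is None else round(c.score, 3),
                        "is_input": c.is_input,
                        "moves": [f"{mv.kind}{mv.sites}" for mv in c.moves],
                    }
                    for c in ranked.candidates[: cfg.revision_top]
                ]

        hits = similarity.dereplicate(p, predicted_spectra)  # step 12
        derep = [
            {
                "rank": h.rank,
                "record": h.record_id,
                "score_ppm": round(h.score, 3),
                "above_threshold": h.above_threshold,
            }
            for h in hits[: cfg.dereplication_top]
        ]

        compound_report = CompoundReport(
            name=name,
            identifier=ident,
            formula_weight=mw,
            verification=report,
            identical_structures=identical,
            pattern_matches=patterns,
            flagged_atoms=flagged,
            revision_rank=rank,
            revision_recommended=recommended,
            revision_table=table,
            dereplication=derep,
        )
        compound_report.verdict = _verdict(compound_report)
        reports.append(compound_report)
    logger.info("workflow finished in %.1f s", time.time() - t0)
    return reports


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def display_delta(delta: Optional[float]) -> str:
    """Deviations larger than 99 ppm are always shown as 99."""
    if delta is None:
        return "n/a"
    capped = min(abs(delta), DISPLAY_CAP)
    return f"{capped:.1f}"


_PROVENANCE_MARK = {"authors": "[assigned]", "exchangeable": "[exchangeable]",
                    "auto": "[auto]", "": ""}


def render_report(report: CompoundReport, fmt: str = "txt") -> str:
    """Human-readable protocol: structure row, experimental row with
    assignment provenance, deviation row with color classification."""
    if fmt not in ("txt", "html"):
        raise ValueError(f"unknown report format {fmt!r}")
    v = report.verification
    lines = [
        f"Compound: {report.name}",
        f"Identifier: {report.identifier}",
        f"MW: {report.formula_weight:.2f} amu",
        f"Verdict: {report.verdict.upper()}",
        "",
        "Findings:",
    ]
    if v.findings:
        for f in v.findings:
            lines.append(f"  [{f.severity}] {f.code}: {f.message}")
    else:
        lines.append("  none")
    lines += ["", "class  atoms          exp(ppm)  pred(ppm)  |diff|  color  provenance"]
    for d in v.deviations:
        atoms = ",".join(str(a) for a in d.atoms)
        exp = "-" if d.experimental is None else f"{d.experimental:8.2f}"
        pred = "-" if d.predicted is None else f"{d.predicted:8.2f}"
        lines.append(
            f"{d.class_id:5d}  {atoms:13s}  {exp:>8s}  {pred:>9s}  "
            f"{display_delta(d.delta):>6s}  {d.color:6s} "
            f"{_PROVENANCE_MARK.get(d.provenance, '')}"
        )
    if v.delta_mean is not None:
        lines.append(f"\nMean |delta| (ppm): {v.delta_mean:.2f}   "
                     f"max: {v.delta_max:.2f}   gross error: "
                     f"{'YES' if v.gross_error else 'no'}")
    if report.pattern_matches:
        lines.append("\nIdentical spectral patterns:")
        for pm in report.pattern_matches:
            tag = " (same data, different structure!)" if pm.same_data_different_structure else ""
            lines.append(
                f"  record {pm.record_id}, max diff {pm.max_difference:.2f} ppm{tag}"
            )
    if report.revision_table:
        lines.append("\nStructure revision (top candidates):")
        for row in report.revision_table:
            marker = " <- input proposal" if row["is_input"] else ""
            lines.append(
                f"  rank {row['rank']:3d}  {row['score_ppm']} ppm  "
                f"{row['identifier']}{marker}"
            )
        if report.revision_recommended:
            lines.append("  REVISION RECOMMENDED: a better-ranked alternative exists")
    if report.dereplication:
        lines.append("\nDereplication (best matches):")
        for row in report.dereplication[:5]:
            flag = " (above reporting threshold)" if row["above_threshold"] else ""
            lines.append(
                f"  rank {row['rank']:3d}  {row['score_ppm']} ppm  {row['record']}{flag}"
            )
    text = "\n".join(lines)
    if fmt == "txt":
        return text
    color_style = {"green": "#2e8b57", "yellow": "#b8860b", "red": "#b22222"}
    rows = []
    for d in v.deviations:
        style = color_style.get(d.color, "#555")
        rows.append(
            f"<tr style='color:{style}'><td>{d.class_id}</td>"
            f"<td>{','.join(map(str, d.atoms))}</td>"
            f"<td>{'' if d.experimental is None else d.experimental}</td>"
            f"<td>{'' if d.predicted is None else round(d.predicted, 2)}</td>"
            f"<td>{display_delta(d.delta)}</td><td>{d.color}</td></tr>"
        )
    return (
        "<html><body><pre>" + text + "</pre><table border='1'>"
        "<tr><th>class</th><th>atoms</th><th>exp</th><th>pred</th>"
        "<th>|diff|</th><th>color</th></tr>" + "".join(rows) + "</table></body></html>"
    )


def write_bundle(
    reports: Sequence[CompoundReport], out_dir: str | Path, fmt: str = "txt"
) -> list[Path]:
    """One machine-readable and one human-readable protocol per compound."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, r in enumerate(reports, start=1):
        stem = f"{i:03d}-{''.join(ch if ch.isalnum() else '-' for ch in r.name)[:40]}"
        jpath = out / f"{stem}.json"
        jpath.write_text(json.dumps(r.to_json_dict(), indent=2))
        tpath = out / f"{stem}.{fmt}"
        tpath.write_text(render_report(r, fmt=fmt))
        written.extend([jpath, tpath])
    return written
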