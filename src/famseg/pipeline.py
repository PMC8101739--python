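"""End-to-end orchestration: simulate -> filter -> assoc -> kinship -> report.

Every run writes a manifest (config snapshot, input digests, seed, tier
counts, timestamps) so each reported number is traceable; the summary
reports the tier funnel and the association table without re-deriving
anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .datamodel import VariantKey
from .filtering import FilterConfig, run_tiered_pipeline
from .io import (
    merge_annotations,
    read_annotations,
    read_count_table,
    read_gene_set,
    read_ped,
    read_vcf,
    write_candidates,
    write_tier_report,
)
from .kinship import kinship_screen, write_kinship_tsv
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .stats import (
    AssociationResult,
    ContingencyTable2x2,
    associate,
    carrier_fraction,
    fisher_exact_two_tailed,
    odds_ratio,
    penetrance_estimate,
    sample_control_counts,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.6g}"


@dataclass
class RunManifest:
    version: str
    seed: Optional[int]
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    complete: bool = False

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def write_association_tsv(results: list[AssociationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("SOURCE\tA\tB\tC\tD\tOR\tP\tP_SCI\n")
        for r in results:
            t = r.table
            fh.write(
                f"{r.source}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{_fmt(r.odds_ratio)}\t"
                f"{_fmt(r.p_two_tailed)}\t{r.p_two_tailed:.3e}\n"
            )


def reproduce_table1(counts_file, out_path=None) -> list[AssociationResult]:
    """Fisher association of printed case counts against each control source.

    The counts file is a SOURCE/POS/NEG table whose case row is named
    ``BPPV`` or ``CASE`` (case-insensitive); every other row is a control
    source. One two-tailed Fisher result per control source.
    """
    rows = read_count_table(counts_file)
    case_rows = [r for r in rows if r[0].upper() in ("BPPV", "CASE", "CASES")]
    if not case_rows:
        raise ValueError(f"{counts_file}: no case row (SOURCE 'BPPV' or 'CASE')")
    controls = [r for r in rows if r not in case_rows]
    if not controls:
        raise ValueError(f"{counts_file}: no control source rows")
    a, b = case_rows[0][1], case_rows[0][2]
    results = []
    for source, c, d in controls:
        table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
        ratio, corrected = odds_ratio(table)
        results.append(
            AssociationResult(
                table=table,
                p_two_tailed=fisher_exact_two_tailed(table),
                odds_ratio=ratio,
                source=source,
                or_corrected=corrected,
            )
        )
    if out_path is not None:
        write_association_tsv(results, out_path)
    return results


def run_all(
    out_dir,
    seed: Optional[int] = None,
    sim_config: Optional[SimulationConfig] = None,
    vcf: Optional[str] = None,
    ped: Optional[str] = None,
    annotations_tsv: Optional[str] = None,
    inner_ear_path: Optional[str] = None,
    balance_path: Optional[str] = None,
    counts_file: Optional[str] = None,
    candidate: Optional[str] = None,
    filter_config: Optional[FilterConfig] = None,
    kinship_threshold: float = 0.125,
) -> Path:
    """Run the full pipeline and write a report directory.

    Either simulate a cohort (``sim_config`` or bare ``seed``) or load one
    from ``vcf``/``ped``/gene-set paths. Outputs: tier_report.tsv,
    prioritized.tsv, association.tsv, kinship.tsv, summary.txt and
    manifest.json. Any stage error marks the manifest incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=seed if sim_config is None else sim_config.seed,
        config={},
        started=time.time(),
    )
    try:
        if vcf is None:
            cfg = sim_config or SimulationConfig(seed=seed if seed is not None else 0)
            manifest.config = asdict(cfg)
            cohort = simulate_cohort(cfg)
            cohort_paths = write_cohort(cohort, out / "cohort")
            manifest.input_digests = {
                name: _sha256(p) for name, p in cohort_paths.items()
            }
            matrix, pedigrees = cohort.matrix, cohort.pedigrees
            annotations = cohort.annotations
            inner_ear, balance = cohort.inner_ear, cohort.balance
            candidate_key = cohort.truth.causal_key
        else:
            for name, p in (("vcf", vcf), ("ped", ped),
                            ("inner_ear", inner_ear_path), ("balance", balance_path)):
                if p is None:
                    raise ValueError(f"missing required input: --{name}")
                manifest.input_digests[name] = _sha256(Path(p))
            matrix, annotations = read_vcf(vcf)
            if annotations_tsv is not None:
                annotations = merge_annotations(annotations, read_annotations(annotations_tsv))
                manifest.input_digests["annotations"] = _sha256(Path(annotations_tsv))
            pedigrees = read_ped(ped)
            inner_ear = read_gene_set(inner_ear_path, "inner_ear")
            balance = read_gene_set(balance_path, "balance")
            candidate_key = VariantKey.parse(candidate) if candidate else None

        fcfg = filter_config or FilterConfig()
        report = run_tiered_pipeline(
            matrix, annotations, pedigrees, inner_ear, balance, fcfg
        )
        manifest.stage_counts = dict(report.counts)
        write_tier_report(report, out / "tier_report.tsv")
        ann_by_key = {a.key: a for a in annotations}
        write_candidates(
            [ann_by_key[p.key] for p in report.prioritized if p.key in ann_by_key],
            out / "prioritized.tsv",
            flags={p.key: p.flags for p in report.prioritized},
        )

        assoc_results: list[AssociationResult] = []
        if candidate_key is None and report.prioritized:
            candidate_key = report.prioritized[0].key
        if candidate_key is not None and matrix.has_variant(candidate_key):
            sources: list[tuple[str, int, int]] = []
            pos, neg = sample_control_counts(pedigrees, matrix, candidate_key)
            sources.append(("sample_controls", pos, neg))
            if counts_file is not None:
                for source, p_, n_ in read_count_table(counts_file):
                    if source.upper() not in ("BPPV", "CASE", "CASES"):
                        sources.append((source, p_, n_))
            assoc_results = associate(pedigrees, matrix, candidate_key, sources)
            write_association_tsv(assoc_results, out / "association.tsv")
            manifest.stage_counts["association_sources"] = len(assoc_results)

        screen = kinship_screen(matrix, pedigrees, threshold=kinship_threshold)
        write_kinship_tsv(screen, pedigrees, out / "kinship.tsv")
        manifest.stage_counts["kinship_flagged"] = len(screen.flagged)

        _write_summary(
            out / "summary.txt", report, assoc_results, screen,
            pedigrees, matrix, candidate_key,
        )
        manifest.complete = True
    except Exception as exc:
        manifest.complete = False
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return out


def _write_summary(path, report, assoc_results, screen, pedigrees, matrix, candidate_key):
    lines = ["== Tier funnel =="]
    for tier in ("impact_pass", "segregating_union", "freq_impact_union",
                 "cross_family", "prioritized"):
        if tier in report.counts:
            lines.append(f"{tier}: {report.counts[tier]}")
    if assoc_results:
        lines.append("")
        lines.append(f"== Association for {candidate_key} ==")
        lines.append("SOURCE\t+/-(cases)\t+/-(controls)\tOR\tP")
        for r in assoc_results:
            t = r.table
            lines.append(
                f"{r.source}\t{t.a}/{t.b}\t{t.c}/{t.d}\t"
                f"{_fmt(r.odds_ratio)}\t{r.p_two_tailed:.3e}"
            )
        if candidate_key is not None and matrix.has_variant(candidate_key):
            try:
                pos, total, pct = carrier_fraction(pedigrees, matrix, candidate_key)
                lines.append(f"carrier families: {pos}/{total} ({pct}%)")
            except ValueError:
                pass
            try:
                pen = penetrance_estimate(pedigrees, matrix, candidate_key)
                lines.append(f"penetrance estimate: {_fmt(pen)}")
            except ValueError:
                pass
    lines.append("")
    lines.append("== Kinship screen ==")
    lines.append(f"cross-family pairs flagged (phi > {screen.threshold}): {len(screen.flagged)}")
    if screen.max_between_phi is not None:
        lines.append(f"max cross-family phi: {_fmt(screen.max_between_phi)}")
    Path(path).write_text("\n".join(lines) + "\n")
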