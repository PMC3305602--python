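"""Summary statistics of an error model.

Reports, per mate sub-model: the overall mismatch, insertion and deletion
rates; the mismatch rate per nucleotide (conditioning on the current base);
the per-cycle rate curves; and the context words whose mismatch rate is an
outlier — more than ``n_sd`` standard deviations above the mean rate over
all sufficiently observed full-length words.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .error_model import BASES, CORRECT, DELETION, INSERTION, ErrorModel, MateModel


@dataclass
class StatsReport:
    """Error statistics for one mate sub-model.  Rates are percentages."""

    overall_mismatch_rate: float
    insertion_rate: float
    deletion_rate: float
    per_nucleotide_rate: dict[str, float]
    # per read position (cycle): mismatch / insertion / deletion rate (%)
    positional_rate: list[float]
    positional_insertion_rate: list[float]
    positional_deletion_rate: list[float]
    positional_bases: list[int]
    n_classified_bases: int
    outlier_words: list[tuple[str, str, float]] = field(default_factory=list)


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def summarize(model: ErrorModel, n_sd: float = 2.0) -> list[StatsReport]:
    """One report per mate sub-model (two for paired models)."""
    return [_summarize_mate(m, model.min_word_count, n_sd) for m in model.mates]


def _summarize_mate(mate: MateModel, x: int, n_sd: float) -> StatsReport:
    tot = mate.total_vector()
    n_classified = int(tot[CORRECT] + tot[1:5].sum())
    n_mm = int(tot[1:5].sum())

    by_base = {b: [0, 0] for b in BASES}  # current base -> [mismatches, classified]
    max_pos = mate.max_position()
    pos_mm = [0] * (max_pos + 1)
    pos_ins = [0] * (max_pos + 1)
    pos_del = [0] * (max_pos + 1)
    pos_bases = [0] * (max_pos + 1)
    for pos, by_word in mate.counts.items():
        for key, vec in by_word.items():
            cur = key.split(".")[1]
            classified = int(vec[CORRECT] + vec[1:5].sum())
            mm = int(vec[1:5].sum())
            if cur in by_base:
                by_base[cur][0] += mm
                by_base[cur][1] += classified
            pos_mm[pos] += mm
            pos_ins[pos] += int(vec[INSERTION])
            pos_del[pos] += int(vec[DELETION])
            pos_bases[pos] += classified

    return StatsReport(
        overall_mismatch_rate=_pct(n_mm, n_classified),
        insertion_rate=_pct(int(tot[INSERTION]), n_classified),
        deletion_rate=_pct(int(tot[DELETION]), n_classified),
        per_nucleotide_rate={b: _pct(mm, cl) for b, (mm, cl) in by_base.items()},
        positional_rate=[_pct(m, b) for m, b in zip(pos_mm, pos_bases)],
        positional_insertion_rate=[_pct(i, b) for i, b in zip(pos_ins, pos_bases)],
        positional_deletion_rate=[_pct(d, b) for d, b in zip(pos_del, pos_bases)],
        positional_bases=pos_bases,
        n_classified_bases=n_classified,
        outlier_words=outlier_words_for_mate(mate, x, n_sd),
    )


def _word_table(mate: MateModel, min_obs: int) -> dict[str, np.ndarray]:
    """Position-marginalized outcome vectors for full-length words."""
    table: dict[str, np.ndarray] = {}
    for by_word in mate.counts.values():
        for key, vec in by_word.items():
            pre, cur, fol = key.split(".")
            if len(pre) != 3 or len(fol) != 1:
                continue  # read-edge truncated words excluded from the scan
            acc = table.get(key)
            if acc is None:
                table[key] = vec.copy()
            else:
                acc += vec
    return {
        k: v
        for k, v in table.items()
        if int(v[CORRECT] + v[1:5].sum()) >= min_obs
    }


def format_substitution(key: str, alt: str) -> str:
    """Render a word and its substitution as e.g. ``GGG**T**A -> GGG**G**A``."""
    pre, cur, fol = key.split(".")
    return f"{pre}**{cur}**{fol} -> {pre}**{alt}**{fol}"


def outlier_words(model: ErrorModel, n_sd: float = 2.0) -> list[list[tuple[str, str, float]]]:
    """Outlier context words per mate: (word key, rendered substitution, rate %)."""
    return [outlier_words_for_mate(m, model.min_word_count, n_sd) for m in model.mates]


def outlier_words_for_mate(
    mate: MateModel, min_obs: int, n_sd: float = 2.0
) -> list[tuple[str, str, float]]:
    table = _word_table(mate, min_obs)
    if len(table) < 2:
        return []
    rates = {}
    for key, vec in table.items():
        classified = int(vec[CORRECT] + vec[1:5].sum())
        rates[key] = int(vec[1:5].sum()) / classified
    mean = statistics.fmean(rates.values())
    sd = statistics.pstdev(rates.values())
    out = []
    for key, rate in rates.items():
        if sd > 0 and rate > mean + n_sd * sd:
            vec = table[key]
            alt = BASES[int(np.argmax(vec[1:5]))]
            out.append((key, format_substitution(key, alt), 100.0 * rate))
    out.sort(key=lambda t: -t[2])
    return out


def render_report(reports: list[StatsReport]) -> str:
    """Plain-text report: overall/per-base rates, outliers, per-cycle TSV."""
    lines = []
    for i, rep in enumerate(reports):
        label = f"read {i + 1}" if len(reports) > 1 else "reads"
        lines.append(f"== Error model statistics ({label}) ==")
        lines.append(f"Overall mismatch rate (%):\t{rep.overall_mismatch_rate:.6g}")
        for b in BASES:
            lines.append(f"{b} mismatch rate (%):\t{rep.per_nucleotide_rate[b]:.6g}")
        lines.append(f"Insertion rate (%):\t{rep.insertion_rate:.6g}")
        lines.append(f"Deletion rate (%):\t{rep.deletion_rate:.6g}")
        for rank, (key, rendered, rate) in enumerate(rep.outlier_words[:5], 1):
            lines.append(f"Outlier {rank}:\t{rendered} ({rate:.3g})")
        lines.append("")
        lines.append("position\tmismatch_pct\tinsertion_pct\tdeletion_pct\tn_bases")
        for p, (mm, ins, de, nb) in enumerate(
            zip(
                rep.positional_rate,
                rep.positional_insertion_rate,
                rep.positional_deletion_rate,
                rep.positional_bases,
            )
        ):
            lines.append(f"{p}\t{mm:.6g}\t{ins:.6g}\t{de:.6g}\t{nb}")
        lines.append("")
    return "\n".join(lines)
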