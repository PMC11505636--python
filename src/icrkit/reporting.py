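"""Plain-text rendering of a comparison report.

Renders the JSON-able dict produced by
:meth:`icrkit.concordance.ComparisonReport.to_dict` as four aligned text
tables (two one-way category tables, the merged cross-tabulation, and
the correlation summary).
"""

from __future__ import annotations


def _freq_block(title: str, cats: list, total: int) -> list[str]:
    lines = [title, f"{'Risk':<12}{'n':>6}{'%':>8}"]
    for label, n, pct in cats:
        pct_s = f"{pct:g}"
        lines.append(f"{label:<12}{n:>6}{pct_s:>8}")
    lines.append(f"{'Total':<12}{total:>6}")
    return lines


def render_report(d: dict) -> str:
    """Text tables for a comparison-report dict."""
    out: list[str] = []
    n = d["n"]
    icr = d["icr"]
    car = d["cariogram_risk"]
    out.append(f"Cohort comparison (N = {n})")
    out.append("")
    out.append(
        f"ICR total score: M = {icr['mean']:.1f} (SD = {icr['sd']:.1f}), "
        f"range {icr['min']:g}-{icr['max']:g}"
    )
    out.append(
        f"Cariogram risk value: M = {car['mean']:.1f}% (SD = {car['sd']:.1f}%), "
        f"range {car['min']:.0f}%-{car['max']:.0f}%"
    )
    out.append("")
    out.extend(_freq_block(f"Caries risk by Cariogram (N = {n})", car["categories"], n))
    out.append("")
    out.extend(_freq_block(f"Caries risk by ICR (N = {n})", icr["categories"], n))
    out.append("")

    ct = d["crosstab"]
    cols = ct["col_labels"]
    out.append("Caries risk assessed merged (rows: ICR, columns: Cariogram)")
    header = f"{'':<12}" + "".join(f"{c:>10}" for c in cols) + f"{'Total':>10}"
    out.append(header)
    for label, row, rt in zip(ct["row_labels"], ct["cells"], ct["row_totals"]):
        out.append(
            f"{label:<12}" + "".join(f"{v:>10}" for v in row) + f"{rt:>10}"
        )
    out.append(
        f"{'Total':<12}"
        + "".join(f"{v:>10}" for v in ct["col_totals"])
        + f"{ct['grand_total']:>10}"
    )
    out.append("")

    corr = d["correlation"]
    pct = int(round(corr["confidence"] * 100))
    out.append(
        f"Pearson correlation (ICR total vs Cariogram risk): "
        f"R = {corr['r']:.2f} (p = {corr['p_value']:.3g}, "
        f"{pct}% CI {corr['ci_low']:.2f}-{corr['ci_high']:.2f}, n = {corr['n']})"
    )
    if d.get("excluded"):
        out.append(f"Excluded (missing one instrument): {', '.join(d['excluded'])}")
    return "\n".join(out) + "\n"
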