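"""Report rendering: machine-readable JSON and a matching text block.

Every number in the text report also appears in the JSON document; the
JSON has a stable field order and a versioned schema so downstream
tooling can re-parse it losslessly.
"""

from __future__ import annotations

import json

from .alleles import EditingSummary, FRAME_CLASSES
from .stats import (
    EssentialityResult,
    class_fractions,
    editing_efficiency,
    inactivation_efficiency,
)

SCHEMA_VERSION = "1.0"


def build_report(
    summary: EditingSummary | None = None,
    result: EssentialityResult | None = None,
    failed_clone_ids: list[str] | None = None,
) -> dict:
    """Assemble the canonical report document."""
    doc: dict = {"schema_version": SCHEMA_VERSION}
    if summary is not None:
        doc["editing_summary"] = summary.to_dict()
        if failed_clone_ids:
            doc["editing_summary"]["failed_clone_ids"] = list(failed_clone_ids)
        if summary.n_sequenced > 0:
            eff = editing_efficiency(summary)
            doc["editing_efficiency"] = {
                "numerator": eff.numerator,
                "denominator": eff.denominator,
                "value": eff.value,
            }
            inact = inactivation_efficiency(summary)
            doc["inactivation_efficiency"] = {
                "numerator": inact.numerator,
                "denominator": inact.denominator,
                "value": inact.value,
            }
        if summary.n_events > 0:
            fin, f1, f2 = class_fractions(summary)
            doc["event_class_fractions"] = {
                "in_frame": fin,
                "frameshift_plus1": f1,
                "frameshift_plus2": f2,
            }
    if result is not None:
        doc["essentiality"] = result.to_dict()
    return doc


def render_text(doc: dict) -> str:
    """Human-readable block mirroring the JSON content."""
    lines: list[str] = [f"CRISPR-E report (schema {doc['schema_version']})"]
    s = doc.get("editing_summary")
    if s:
        lines.append(
            f"clones: {s['n_clones']} total = {s['n_failed']} failed "
            f"+ {s['n_sequenced']} sequenced "
            f"({s['n_wt']} WT + {s['n_edited']} edited)"
        )
        if s.get("failed_clone_ids"):
            lines.append(
                f"failed sequencing ({s['n_failed']}): "
                + ", ".join(s["failed_clone_ids"])
            )
        lines.append(f"independent editing events: {s['n_events']}")
        counts = s["event_class_counts"]
        lines.append(
            "event classes: "
            + ", ".join(f"{c}={counts.get(c, 0)}" for c in FRAME_CLASSES)
        )
        if s.get("n_stop_gain_events"):
            lines.append(
                f"in-frame events with a gained stop codon: "
                f"{s['n_stop_gain_events']}"
            )
        if s.get("n_outside_window"):
            lines.append(
                f"clones with edits only outside the window (counted WT at "
                f"target): {s['n_outside_window']}"
            )
    eff = doc.get("editing_efficiency")
    if eff:
        lines.append(
            f"editing efficiency (edited clones / sequenced clones): "
            f"{100 * eff['value']:.1f}% ({eff['numerator']} out of "
            f"{eff['denominator']})"
        )
    inact = doc.get("inactivation_efficiency")
    if inact:
        lines.append(
            f"inactivation efficiency (frameshift clones / sequenced clones): "
            f"{100 * inact['value']:.1f}% ({inact['numerator']} out of "
            f"{inact['denominator']})"
        )
    frac = doc.get("event_class_fractions")
    if frac:
        lines.append(
            f"class fractions over events: in-frame {100 * frac['in_frame']:.0f}%, "
            f"3n+1 {100 * frac['frameshift_plus1']:.0f}%, "
            f"3n+2 {100 * frac['frameshift_plus2']:.0f}%"
        )
    e = doc.get("essentiality")
    if e:
        lines.append(
            f"k = {e['k']} independent edited events, "
            f"x = {e['x_frameshift']} frameshift"
        )
        lines.append(
            f"P(all in-frame | neutral) = (1 - {e['f_exp']:.4g})^{e['k']} "
            f"= {e['p_all_in_frame']:.4g}"
        )
        lines.append(f"one-sided exact frameshift-deficit P = {e['p_deficit']:.4g}")
        lines.append(
            f"E = {e['E']:.3g} "
            f"[{100 * e['confidence']:.0f}% CI {e['E_ci'][0]:.3g}"
            f"-{e['E_ci'][1]:.3g}]"
        )
        lines.append(f"verdict: {e['verdict']}")
    return "\n".join(lines) + "\n"


def dump_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
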