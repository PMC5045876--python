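"""Sequential combination of barrier strengths into cumulative contributions.

Barriers act in the order they occur in the life cycle: each barrier can only
remove the gene flow that earlier barriers let through. With per-stage
strengths s_1..s_k,

    AC_1 = s_1
    AC_n = s_n * (1 - sum_{i<n} AC_i)          (absolute contribution)
    T    = sum_n AC_n = 1 - prod_n (1 - s_n)   (total isolation)
    RC_n = AC_n / T                            (relative contribution)

The total is invariant to barrier order (it is one minus a product), while
the split into absolute contributions is order-dependent — which is exactly
why reporting the sequential decomposition requires fixing an order.
"""

from __future__ import annotations

import math
import warnings
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence

from .datamodel import BarrierEstimate, CascadeResult, ValidationError
from .metrics import barrier_from_crosses, barrier_from_sharing, ri_cooccurrence, ri_symmetric

REPORT_COLUMNS = (
    "barrier",
    "stage",
    "raw_1",
    "raw_2",
    "ri_value",
    "absolute_cumulative",
    "relative_cumulative",
)


def build_barriers(
    raw_rows,
    post_strength_formula: str = "proportional",
    order: Optional[Sequence[str]] = None,
) -> list[BarrierEstimate]:
    """Turn (name, stage, payload) triples into cascade-ready barrier estimates.

    Pre-pollination rows take the co-occurrence metric as strength;
    post-pollination rows use ``post_strength_formula`` (``proportional`` by
    default, ``symmetric`` as the alternative). ``order`` selects and orders
    barriers by name; the default keeps input order.
    """
    by_name = {}
    for name, stage, payload in raw_rows:
        if stage == "pre":
            by_name[name] = barrier_from_sharing(payload, name)
        else:
            by_name[name] = barrier_from_crosses(payload, name, strength_metric=post_strength_formula)
    names = list(order) if order else [name for name, _stage, _payload in raw_rows]
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValidationError(f"unknown barrier name(s) in order: {', '.join(missing)}")
    return [by_name[n] for n in names]


def sequential_cascade(barriers: Sequence[BarrierEstimate]) -> CascadeResult:
    """Compute absolute and relative cumulative contributions in the given order.

    Negative strengths (heterospecific advantage) are propagated faithfully —
    the corresponding absolute contribution is negative and the total
    decreases — with a warning.
    """
    if not barriers:
        raise ValidationError("sequential_cascade requires at least one barrier")
    strengths = tuple(float(b.strength) for b in barriers)
    if any(s < 0 for s in strengths):
        warnings.warn("cascade contains negative barrier strengths; total may decrease", stacklevel=2)
    absolute = []
    remaining = 1.0
    for s in strengths:
        ac = s * remaining
        absolute.append(ac)
        remaining -= ac
    total = math.fsum(absolute)
    relative: Optional[tuple[float, ...]]
    if total == 0.0:
        relative = None
    else:
        relative = tuple(ac / total for ac in absolute)
    return CascadeResult(
        order=tuple(b.name for b in barriers),
        strengths=strengths,
        absolute=tuple(absolute),
        relative=relative,
        total=total,
    )


def total_isolation(result: CascadeResult) -> float:
    """Total isolation T, cross-checked against the product identity.

    T must equal ``1 - prod(1 - s_i)`` up to floating-point round-off; a
    discrepancy indicates a corrupted result object.
    """
    prod = 1.0
    for s in result.strengths:
        prod *= 1.0 - s
    identity = 1.0 - prod
    if abs(result.total - identity) > 1e-9:
        raise ValidationError(
            f"cascade total {result.total!r} violates the product identity {identity!r}"
        )
    return result.total


def round_half_even(x: float, digits: int) -> float:
    """Banker's rounding on the decimal representation (display only)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def truncate_decimals(x: float, digits: int) -> float:
    """Truncate toward zero at ``digits`` decimals (display only).

    Published barrier tables print the mating-based RI column truncated
    rather than rounded (0.62963 appears as 0.629), so the report applies
    the same convention to that column to stay bit-compatible.
    """
    # Absorb binary round-off (e.g. 0.19999999999999996) before truncating.
    guarded = Decimal(repr(x)).quantize(Decimal(1).scaleb(-(digits + 6)), rounding=ROUND_HALF_EVEN)
    return float(guarded.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_DOWN))


def render_barrier_report(
    barriers: Sequence[BarrierEstimate],
    result: CascadeResult,
    precision: int = 3,
    fmt: str = "text",
) -> str:
    """Render the per-barrier contribution table.

    One row per barrier — name, stage, raw value pair, displayed RI value
    (co-occurrence metric for pre-pollination rows, symmetric metric for
    post-pollination rows), absolute and relative cumulative contribution —
    plus a TOTAL row. Numbers are rounded half-even at ``precision`` decimals
    for display only — except the RI-value column, which is truncated toward
    zero (see :func:`truncate_decimals`). Internal values are never rounded
    between stages.

    The displayed relative contribution is the *rounded* absolute
    contribution divided by the unrounded total, so that the printed AC and
    RC columns are mutually consistent at the chosen precision.

    ``fmt`` is ``"text"`` (aligned columns) or ``"tsv"``.
    """
    if tuple(b.name for b in barriers) != result.order:
        raise ValidationError("barrier list does not match the cascade result order")
    if fmt not in ("text", "tsv"):
        raise ValidationError(f"unknown report format {fmt!r}")

    def fnum(x: float) -> str:
        return f"{round_half_even(x, precision):.{precision}f}"

    def fri(x: float) -> str:
        return f"{truncate_decimals(x, precision):.{precision}f}"

    rows = [list(REPORT_COLUMNS)]
    flagged = False
    for b, ac in zip(barriers, result.absolute):
        if b.stage == "pre":
            raw1, raw2 = b.raw.shared_fraction, b.raw.unshared_fraction
            ri_value = b.ri_cooccurrence if b.ri_cooccurrence is not None else ri_cooccurrence(b.raw).value
        else:
            raw1, raw2 = b.raw.heterospecific_success, b.raw.conspecific_success
            ri_value = b.ri_symmetric if b.ri_symmetric is not None else ri_symmetric(b.raw).value
        if b.strength < 0 or ac < 0:
            flagged = True
        rc_display = "" if result.total == 0 else fnum(round_half_even(ac, precision) / result.total)
        name = b.name + (" [negative]" if b.strength < 0 or ac < 0 else "")
        rows.append([name, b.stage, fnum(raw1), fnum(raw2), fri(ri_value), fnum(ac), rc_display])
    rows.append(["TOTAL", "", "", "", "", fnum(result.total), "" if result.total == 0 else fnum(1.0)])

    if fmt == "tsv":
        body = "\n".join("\t".join(r) for r in rows)
    else:
        widths = [max(len(r[i]) for r in rows) for i in range(len(REPORT_COLUMNS))]
        body = "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows)
    if flagged:
        body += "\nnote: one or more barriers have negative strength (heterospecific advantage)"
    return body + "\n"
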