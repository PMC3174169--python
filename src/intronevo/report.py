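"""Densities, branch gain/loss percentages, phase tallies, reports.

Ancestral intron *counts* live on the scale of the analyzed table; to
compare across studies they are converted to intron *densities*
(introns per kbp of coding sequence) by anchoring to a reference
species present in the data:

    density = count · ref_density / ref_count

The default reference is human: 6.946 introns/kbp mean density in the
analyzed genes, 875 human introns in the table those defaults came
from.  For synthetic datasets supply the generator's own reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import PRESENT, ProfileTable
from .trees import SpeciesTree

#: human anchor: mean introns/kbp in the analyzed coding sequences
HUMAN_DENSITY_PER_KBP = 6.946
#: human intron count in the reference table
HUMAN_REF_COUNT = 875


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class DensityReference:
    """Anchor converting intron counts to introns-per-kbp densities."""

    ref_count: float = HUMAN_REF_COUNT
    ref_density: float = HUMAN_DENSITY_PER_KBP

    def __post_init__(self) -> None:
        if self.ref_count <= 0 or self.ref_density <= 0:
            raise ReportError("reference count and density must be positive")

    @classmethod
    def from_table(cls, table: ProfileTable, species: str,
                   ref_density: float = HUMAN_DENSITY_PER_KBP
                   ) -> "DensityReference":
        """Recompute ref_count as the species' presence total in the table."""
        if species not in table.species:
            raise ReportError(f"reference species {species!r} not in table")
        i = table.species.index(species)
        count = int((table.entries[i] == PRESENT).sum())
        if count == 0:
            raise ReportError(f"{species!r} has no introns in the table")
        return cls(ref_count=count, ref_density=ref_density)


def counts_to_density(count: float, ref: DensityReference) -> float:
    """Convert an intron count to introns per kbp (linear in count)."""
    if count < 0:
        raise ReportError("count must be >= 0")
    return count * ref.ref_density / ref.ref_count


def percent_of_reference(density: float, ref: DensityReference) -> float:
    """Density as a percentage of the reference species' density."""
    if density < 0:
        raise ReportError("density must be >= 0")
    return 100.0 * density / ref.ref_density


def branch_gain_loss_percent(gains: float, losses: float,
                             parent_count: float, child_count: float
                             ) -> tuple[float, float, bool]:
    """Per-edge (gain%, loss%) relative to child and parent counts.

    gain% is the percentage of the child's introns gained on the edge
    (100·gains/child count); loss% is the percentage of the parent's
    introns lost (100·losses/parent count).  A zero denominator yields
    0 with the returned flag set.
    """
    if min(gains, losses, parent_count, child_count) < 0:
        raise ReportError("gain/loss percentages need non-negative inputs")
    flagged = False
    if child_count > 0:
        gain_pct = 100.0 * gains / child_count
    else:
        gain_pct, flagged = 0.0, True
    if parent_count > 0:
        loss_pct = 100.0 * losses / parent_count
    else:
        loss_pct, flagged = 0.0, True
    return gain_pct, loss_pct, flagged


def phase_tally(presence: np.ndarray, gain: np.ndarray, loss: np.ndarray,
                phases: np.ndarray, node_names: list[str]) -> pd.DataFrame:
    """Phase-stratified tallies of present/gained/lost introns.

    ``presence``/``gain``/``loss`` are per-site × per-node probability
    (or 0/1 history) matrices; ``phases`` maps each site to phase
    0/1/2.  Returns one row per (node, phase) with the three tallies;
    within each node the three phases partition the unstratified total.
    """
    phases = np.asarray(phases)
    if presence.shape[0] != phases.shape[0]:
        raise ReportError("phase annotation does not cover all sites")
    if not np.isin(phases, [0, 1, 2]).all():
        raise ReportError("phases must be 0/1/2")
    rows = []
    for u, name in enumerate(node_names):
        for ph in (0, 1, 2):
            sel = phases == ph
            rows.append({
                "node": name, "phase": ph,
                "present": float(presence[sel, u].sum()),
                "gained": float(gain[sel, u].sum()),
                "lost": float(loss[sel, u].sum()),
            })
    return pd.DataFrame(rows)


def assemble_report(method_results: dict[str, dict[str, float]],
                    tree: SpeciesTree,
                    ref: DensityReference,
                    edge_events: dict[str, dict[str, tuple[float, float]]]
                    | None = None,
                    intervals: dict[str, tuple[float, float]] | None = None
                    ) -> pd.DataFrame:
    """One row per (node, method): count, density, interval, gain%/loss%.

    ``method_results`` maps method name → {node name → count}; every
    method must cover the same node set (the tree's).  ``intervals``
    (MCMC only) maps node → (lo, hi) counts.  Full precision is kept;
    presentation rounding is left to the caller.
    """
    node_set = set(tree.names)
    for method, counts in method_results.items():
        if set(counts) != node_set:
            raise ReportError(f"method {method!r} reports a different node set")
    rows = []
    for method, counts in sorted(method_results.items()):
        events = (edge_events or {}).get(method, {})
        for name in sorted(tree.names):
            u = tree.names.index(name)
            count = counts[name]
            row = {
                "node": name,
                "method": method,
                "count": count,
                "density": counts_to_density(max(count, 0.0), ref),
                "pct_of_reference": percent_of_reference(
                    counts_to_density(max(count, 0.0), ref), ref),
            }
            if u != tree.root and name in events:
                g, l = events[name]
                parent_count = counts[tree.names[tree.parent[u]]]
                gp, lp, flag = branch_gain_loss_percent(g, l, parent_count,
                                                        count)
                row.update({"gains": g, "losses": l, "gain_pct": gp,
                            "loss_pct": lp, "pct_flagged": flag})
            if method == "mcmc" and intervals and name in intervals:
                lo, hi = intervals[name]
                row["count_lo"] = lo
                row["count_hi"] = hi
                row["density_lo"] = counts_to_density(max(lo, 0.0), ref)
                row["density_hi"] = counts_to_density(max(hi, 0.0), ref)
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["node", "method"]).reset_index(drop=True)
    if len(method_results) > 1 and "mcmc" in method_results:
        base = df[df.method == "mcmc"].set_index("node")["count"]
        df["diff_vs_mcmc"] = df.apply(
            lambda r: r["count"] - base[r["node"]], axis=1)
    return df


def round_for_display(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: densities to 1 decimal, percentages to int."""
    out = df.copy()
    for c in out.columns:
        if c.startswith("density"):
            out[c] = out[c].round(1)
        elif c.endswith("_pct") or c == "pct_of_reference":
            out[c] = out[c].round(0).astype("Int64", errors="ignore")
    return out
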