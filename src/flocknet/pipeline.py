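"""Full-experiment analysis: networks per context and period, imposed
assortment against permutation nulls, and cross-context consistency.

The driver mirrors the structure of the field experiment's results:

* assortment by tag parity per social context (selective feeders,
  ephemeral patches, nest-boxes) and period (pre / during / post);
* windowed network-consistency curves, comparing each consecutive
  window's feeder network to the final pre-manipulation window and to the
  post-manipulation network;
* lagged cross-context comparisons (patch deployments vs. the feeder
  network immediately preceding them; nest-box networks vs. simultaneous
  feeder networks), each as a Mantel test plus an MRQAP-DSP separating
  the feeder social network from binary spatial range overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from flocknet.assortment import node_permutation_null
from flocknet.config import (
    CONTEXT_FEEDER,
    CONTEXT_NESTBOX,
    CONTEXT_PATCH,
    PERIOD_DURING,
    PERIOD_POST,
    PERIOD_PRE,
    PERIODS,
    SECONDS_PER_DAY,
    AnalysisPlan,
    ScenarioConfig,
)
from flocknet.groups import daily_nestbox_groups, detect_events, events_to_gbi
from flocknet.matrixstats import mantel, mrqap_dsp
from flocknet.networks import (
    AssociationNetwork,
    common_roster,
    hwi,
    spatial_overlap,
    subset,
    window_networks,
)
from flocknet.synthetic import ScenarioData, simulate_scenario

_SEED_ASSORT = 0
_SEED_CONSISTENCY = 1
_SEED_COMPARE = 2


@dataclass
class ResultsBundle:
    """All report tables from one full analysis, plus the networks behind them."""

    assortment: pd.DataFrame
    consistency: pd.DataFrame
    comparisons: pd.DataFrame
    overlap: pd.DataFrame
    networks: dict = field(default_factory=dict)
    plan: AnalysisPlan | None = None
    config: ScenarioConfig | None = None

    def write(self, out_dir: str | Path) -> None:
        from flocknet.io import write_graphml, write_json, write_provenance

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params = {
            "n_perm": self.plan.n_perm if self.plan else None,
            "window_days": self.plan.window_days if self.plan else None,
        }
        seed = self.plan.seed if self.plan else None
        for name in ("assortment", "consistency", "comparisons", "overlap"):
            df = getattr(self, name)
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            write_provenance(path, {"table": name}, params, seed)
        write_json(
            {"assortment": self.assortment.to_dict(orient="records")},
            out / "assortment.json",
        )
        write_provenance(out / "assortment.json", {"table": "assortment"},
                         params, seed)
        for key, net in self.networks.items():
            if net is not None and net.n_nodes > 0:
                write_graphml(net, out / f"network_{key}.graphml")


def roster_overlap_percent(n_shared: int, n_context: int) -> int:
    """Share of a context's roster also seen at the feeders, as the nearest
    integer percent (how cross-context coverage is reported)."""
    if n_context <= 0:
        raise ValueError("n_context must be positive")
    return round(100.0 * n_shared / n_context)


def _day_filter(det: pd.DataFrame, day_lo: int, day_hi: int) -> pd.DataFrame:
    day = det["timestamp"] // SECONDS_PER_DAY
    return det[(day >= day_lo) & (day < day_hi)]


def feeder_network(
    detections: pd.DataFrame,
    day_lo: int,
    day_hi: int,
    plan: AnalysisPlan,
    provenance: dict | None = None,
) -> AssociationNetwork | None:
    """Feeder association network over scenario days [day_lo, day_hi)."""
    det = detections[detections["context"] == CONTEXT_FEEDER]
    if not plan.include_denied_visits:
        det = det[det["access_granted"]]
    det = _day_filter(det, day_lo, day_hi)
    if det.empty:
        return None
    events = detect_events(det, plan.segmentation)
    if not events:
        return None
    prov = {"context": CONTEXT_FEEDER, "day_lo": day_lo, "day_hi": day_hi}
    prov.update(provenance or {})
    return hwi(events_to_gbi(events), provenance=prov)


def patch_network(
    detections: pd.DataFrame, day_lo: int, day_hi: int, plan: AnalysisPlan
) -> AssociationNetwork | None:
    det = _day_filter(detections[detections["context"] == CONTEXT_PATCH],
                      day_lo, day_hi)
    if det.empty:
        return None
    events = detect_events(det, plan.segmentation)
    if not events:
        return None
    return hwi(events_to_gbi(events),
               provenance={"context": CONTEXT_PATCH, "day_lo": day_lo,
                           "day_hi": day_hi})


def nestbox_network(
    detections: pd.DataFrame, day_lo: int, day_hi: int
) -> AssociationNetwork | None:
    det = _day_filter(detections[detections["context"] == CONTEXT_NESTBOX],
                      day_lo, day_hi)
    if det.empty:
        return None
    events = daily_nestbox_groups(det)
    if not events:
        return None
    return hwi(events_to_gbi(events),
               provenance={"context": CONTEXT_NESTBOX, "day_lo": day_lo,
                           "day_hi": day_hi})


def _assort_row(net: AssociationNetwork | None, context: str, period: str,
                plan: AnalysisPlan, rng: np.random.Generator) -> dict:
    row = {"context": context, "period": period, "r": np.nan, "se": np.nan,
           "null_lo": np.nan, "null_hi": np.nan, "p": np.nan,
           "n_perm": plan.n_perm, "n_nodes": 0, "seed": plan.seed}
    if net is None or net.n_nodes < 3:
        return row
    try:
        res = node_permutation_null(net, n_perm=plan.n_perm, seed=rng)
    except ValueError:
        return row
    row.update(res.to_dict())
    row["n_nodes"] = res.n_nodes
    return row


def run_full_analysis(
    data: ScenarioData | ScenarioConfig | pd.DataFrame,
    plan: AnalysisPlan | None = None,
    config: ScenarioConfig | None = None,
) -> ResultsBundle:
    """Run the complete analysis chain on a scenario or detection stream.

    ``data`` may be a ScenarioConfig (simulated first), a ScenarioData, or
    a raw detection DataFrame (then ``config`` supplies the period
    boundaries and context schedule).
    """
    plan = plan or AnalysisPlan()
    if isinstance(data, ScenarioConfig):
        data = simulate_scenario(data)
    if isinstance(data, ScenarioData):
        detections, config = data.detections, data.config
    else:
        detections = data
        if config is None:
            raise ValueError("config required when passing raw detections")
    if detections.empty:
        raise ValueError("no detections to analyse")

    starts = config.period_starts_days
    lengths = dict(zip(PERIODS, config.period_lengths_days))
    bounds = {p: (starts[p], starts[p] + lengths[p]) for p in PERIODS}

    networks: dict[str, AssociationNetwork | None] = {}
    for period in PERIODS:
        lo, hi = bounds[period]
        networks[f"{CONTEXT_FEEDER}_{period}"] = feeder_network(
            detections, lo, hi, plan, provenance={"period": period}
        )
        networks[f"{CONTEXT_PATCH}_{period}"] = patch_network(
            detections, lo, hi, plan
        )
        networks[f"{CONTEXT_NESTBOX}_{period}"] = nestbox_network(
            detections, lo, hi
        )

    # (i) assortment by tag parity per context x period
    rng_assort = np.random.default_rng([plan.seed, _SEED_ASSORT])
    assort_rows = []
    for context in (CONTEXT_FEEDER, CONTEXT_PATCH, CONTEXT_NESTBOX):
        for period in PERIODS:
            net = networks[f"{context}_{period}"]
            if net is None:
                continue
            assort_rows.append(
                _assort_row(net, context, period, plan, rng_assort)
            )
    assortment = pd.DataFrame(assort_rows)

    # (ii) windowed consistency curves at the feeders
    feeder_det = detections[detections["context"] == CONTEXT_FEEDER]
    if not plan.include_denied_visits:
        feeder_det = feeder_det[feeder_det["access_granted"]]
    windows: list[AssociationNetwork] = []
    for period in PERIODS:
        lo, hi = bounds[period]
        per_det = _day_filter(feeder_det, lo, hi)
        if per_det.empty:
            continue
        nets = window_networks(
            per_det, plan.window_days, plan.segmentation, start_day=lo
        )
        for net in nets:
            net.provenance["period"] = period
        windows.extend(nets)
    ref_pre = feeder_network(
        detections, bounds[PERIOD_PRE][1] - plan.window_days,
        bounds[PERIOD_PRE][1], plan, provenance={"reference": "final_pre"},
    )
    ref_post = networks[f"{CONTEXT_FEEDER}_{PERIOD_POST}"]
    consistency = consistency_curves(
        windows, ref_pre, ref_post, n_perm=plan.n_perm, n_boot=plan.n_boot,
        seed=np.random.default_rng([plan.seed, _SEED_CONSISTENCY]),
    )

    # (iii) lagged cross-context comparisons (Mantel + MRQAP-DSP)
    rng_cmp = np.random.default_rng([plan.seed, _SEED_COMPARE])
    cmp_rows = []
    patch_windows = [
        (PERIOD_PRE, d) for d in config.patch_starts_pre
    ] + [(PERIOD_DURING, starts[PERIOD_DURING] + d)
         for d in config.patch_starts_during]
    for period, day in patch_windows:
        dep = patch_network(detections, day, day + config.patch_days, plan)
        row = _compare_row(
            detections, dep, CONTEXT_PATCH, period, day - plan.patch_lag_days,
            day, f"d{day}-d{day + config.patch_days - 1}", plan, rng_cmp,
        )
        if row:
            cmp_rows.append(row)

    post_start = starts[PERIOD_POST]
    split = plan.nestbox_split_days
    box_chunks = [
        (PERIOD_DURING, post_start - 2 * split),
        (PERIOD_DURING, post_start - split),
        (PERIOD_POST, post_start),
        (PERIOD_POST, post_start + split),
    ]
    for period, day in box_chunks:
        dep = nestbox_network(detections, day, day + split)
        row = _compare_row(
            detections, dep, CONTEXT_NESTBOX, period, day, day + split,
            f"d{day}-d{day + split - 1}", plan, rng_cmp,
        )
        if row:
            cmp_rows.append(row)
    comparisons = pd.DataFrame(cmp_rows)

    # (iv) cross-context roster overlap with the feeders, during manipulation
    overlap_rows = []
    feeder_during = networks[f"{CONTEXT_FEEDER}_{PERIOD_DURING}"]
    if feeder_during is not None:
        feeder_set = set(feeder_during.roster)
        for context in (CONTEXT_PATCH, CONTEXT_NESTBOX):
            net = networks[f"{context}_{PERIOD_DURING}"]
            if net is None or net.n_nodes == 0:
                continue
            inter = len(set(net.roster) & feeder_set)
            overlap_rows.append(
                {
                    "context": context,
                    "period": PERIOD_DURING,
                    "n_context": net.n_nodes,
                    "n_shared_with_feeders": inter,
                    "percent_shared": roster_overlap_percent(inter, net.n_nodes),
                }
            )
    overlap = pd.DataFrame(overlap_rows)

    return ResultsBundle(
        assortment=assortment, consistency=consistency,
        comparisons=comparisons, overlap=overlap, networks=networks,
        plan=plan, config=config,
    )


def _compare_row(
    detections: pd.DataFrame,
    dep: AssociationNetwork | None,
    context: str,
    period: str,
    feeder_lo: int,
    feeder_hi: int,
    days_label: str,
    plan: AnalysisPlan,
    rng: np.random.Generator,
) -> dict | None:
    """One Table-row comparison: dep context network vs. feeder social +
    spatial overlap over the matched feeder window."""
    if dep is None or dep.n_nodes < 4:
        return None
    social = feeder_network(detections, feeder_lo, feeder_hi, plan)
    if social is None:
        return None
    feeder_det = _day_filter(
        detections[detections["context"] == CONTEXT_FEEDER], feeder_lo, feeder_hi
    )
    spatial = spatial_overlap(feeder_det)
    try:
        roster = common_roster(dep, social, spatial, min_size=4)
    except ValueError:
        return None
    dep_c, social_c, spatial_c = (
        subset(dep, roster), subset(social, roster), subset(spatial, roster)
    )
    man = mantel(dep_c, social_c, n_perm=plan.n_perm, n_boot=plan.n_boot,
                 seed=rng)
    try:
        qap = mrqap_dsp(
            dep_c, {"social": social_c.W, "spatial": spatial_c.B.astype(float)},
            n_perm=plan.n_perm, seed=rng,
        )
    except ValueError:
        return None
    return {
        "context": context,
        "period": period,
        "days": days_label,
        "mantel_lo": man.ci_lo,
        "mantel_r": man.r,
        "mantel_hi": man.ci_hi,
        "mantel_p": man.p_perm,
        "social_coeff": qap.coefficients["social"],
        "social_p": qap.p_dsp["social"],
        "spatial_coeff": qap.coefficients["spatial"],
        "spatial_p": qap.p_dsp["spatial"],
        "F": qap.F_full,
        "r2": qap.r2_full,
        "n_common": len(roster),
    }


def consistency_curves(
    windows: list[AssociationNetwork],
    reference_pre: AssociationNetwork | None,
    reference_post: AssociationNetwork | None,
    n_perm: int = 1_000,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mantel similarity of each windowed network to two reference networks.

    Each window is aligned to the common individuals of each comparison;
    windows sharing fewer than 3 individuals with a reference yield NaN
    for that reference rather than an error.
    """
    if reference_pre is None and reference_post is None:
        raise ValueError("at least one reference network is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for w, net in enumerate(windows):
        row: dict = {
            "window": w,
            "period": net.provenance.get("period", ""),
            "start_day": net.provenance.get("window_start_day", np.nan),
            "n_nodes": net.n_nodes,
        }
        for label, ref in (("pre", reference_pre), ("post", reference_post)):
            r = lo = hi = p = np.nan
            n_common = 0
            if ref is not None and net.n_nodes >= 3:
                try:
                    a, b = _aligned(net, ref)
                    n_common = a.n_nodes
                    res = mantel(a, b, n_perm=n_perm, n_boot=n_boot, seed=rng)
                    r, lo, hi, p = res.r, res.ci_lo, res.ci_hi, res.p_perm
                except ValueError:
                    pass
            row.update({f"r_vs_{label}": r, f"ci_lo_vs_{label}": lo,
                        f"ci_hi_vs_{label}": hi, f"p_vs_{label}": p,
                        f"n_common_vs_{label}": n_common})
        rows.append(row)
    return pd.DataFrame(rows)


def _aligned(a: AssociationNetwork, b: AssociationNetwork):
    roster = common_roster(a, b)
    return subset(a, roster), subset(b, roster)
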