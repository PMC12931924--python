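"""End-to-end orchestration: simulate or load a session, gate units, measure
Fano-factor and shared-variance size tuning, fit tuning functions, and emit
per-unit tables plus a machine-readable per-layer summary.

Every stochastic step derives its seed from the run seed, so a run is
idempotent: the same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .datamodel import (BASELINE_WINDOW_MS, FIG_AVG_WINDOW_MS, LAYERS,
                        STIM_WINDOW_MS, TrialSpikeData, count_in_window,
                        load_session)
from .preprocess import is_size_tuned, is_visually_responsive
from .shared import shared_variance_size_tuning
from .tuning import (S_MAX_DEG, canonical_size_values, correlate_ff_change_with_si,
                     fit_double_rog, fit_rate_rog, rf_diameter, rog,
                     suppression_index, surround_diameter)
from .variability import (PCT_CHANGE_EXCLUSION, bootstrap_ff_sd,
                          classify_unit_modulation, fano_factor, median_zero_test)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "make_report"]

#: the % -change contrasts reported per layer: (label, numerator, denominator)
FF_CONTRASTS = ("rf_vs_baseline", "near_vs_rf", "surround_vs_rf", "far_vs_rf")
SV_CONTRASTS = ("near_vs_rf", "far_vs_rf")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    seed: int = 0
    input_path: str | None = None        # None -> simulate
    # synthetic-session shape (used when input_path is None)
    n_penetrations: int = 5
    channels_per_penetration: int = 24
    n_diameters: int = 12
    trials_per_diameter: int = 30
    # analysis choices
    analysis_window: str = "standard"    # 'standard' [50,450) or 'fig' [50,350)
    B_median: int = 9999
    B_classify: int = 3000
    B_err: int = 1000
    rate_restarts: int = 20
    double_restarts: int = 50
    fa_q: int = 1
    out_dir: str | None = None

    @property
    def window_ms(self) -> tuple[float, float]:
        if self.analysis_window == "standard":
            return STIM_WINDOW_MS
        if self.analysis_window == "fig":
            return FIG_AVG_WINDOW_MS
        raise ValueError(f"unknown analysis window {self.analysis_window!r}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change them
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _child_seed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _round(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            return None
        return float(f"{float(obj):.{ndigits}g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _median_block(changes: np.ndarray, B_median: int, B_err: int, seed: int) -> dict:
    """Median % change with bootstrap SD of the median and a two-sided
    zero-median bootstrap p (plus the one-sided p in the median's direction)."""
    out = {"n": int(changes.size)}
    if changes.size < 5 or np.all(changes == changes[0]):
        out.update({"median": float(np.median(changes)) if changes.size else None,
                    "boot_sd": None, "p_two_sided": None, "p_directional": None})
        return out
    med = float(np.median(changes))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, changes.size, size=(B_err, changes.size))
    boot_sd = float(np.median(changes[idx], axis=1).std(ddof=1))
    tail = "greater" if med > 0 else "less"
    out.update({
        "median": med,
        "boot_sd": boot_sd,
        "p_two_sided": median_zero_test(changes, B=B_median, tail="two-sided", seed=seed),
        "p_directional": median_zero_test(changes, B=B_median, tail=tail, seed=seed),
    })
    return out


def run_full_analysis(config: RunConfig, session: TrialSpikeData | None = None):
    """Run preprocessing -> variability -> tuning -> shared variability.

    Returns ``(summary, per_unit_table)``; if ``config.out_dir`` is set, the
    summary JSON, per-unit CSV and run config are written there (a cached
    summary with the same config hash is reused).
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    chash = config.config_hash()
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cached = out_dir / "summary.json"
        if cached.exists():
            summary = json.loads(cached.read_text())
            if summary.get("config_hash") == chash:
                logger.info("reusing cached summary (config hash %s)", chash)
                table = pd.read_csv(out_dir / "per_unit.csv")
                return summary, table

    if session is None:
        if config.input_path is not None:
            session = load_session(config.input_path)
        else:
            scfg = synth.default_config(
                seed=config.seed,
                n_penetrations=config.n_penetrations,
                channels_per_penetration=config.channels_per_penetration,
                n_diameters=config.n_diameters,
                trials_per_diameter=config.trials_per_diameter,
            )
            session, _ = synth.simulate_session(scfg)

    window = config.window_ms
    T_s = (window[1] - window[0]) / 1000.0
    stim = count_in_window(session, *window, label="stim")
    gate = count_in_window(session, *FIG_AVG_WINDOW_MS, label="gate")
    base = count_in_window(session, *BASELINE_WINDOW_MS, label="baseline")
    diameters = session.diameters
    s_min = float(diameters[0])

    rows = []
    per_layer_changes: dict[str, dict[str, list]] = {
        lay: {c: [] for c in FF_CONTRASTS} for lay in LAYERS}
    per_layer_sv: dict[str, dict[str, list]] = {
        lay: {c: [] for c in SV_CONTRASTS} for lay in LAYERS}
    per_layer_si: dict[str, list] = {lay: [] for lay in LAYERS}
    census = {lay: {"amplifier": 0, "quencher": 0, "neither": 0} for lay in LAYERS}

    sv_res = shared_variance_size_tuning(
        session, seed=_child_seed(config.seed, "fa"), q=config.fa_q,
        n_restarts=config.double_restarts)
    sv_fits = sv_res["fits"]

    for ui, unit in enumerate(session.units):
        uid = unit.unit_id
        stage = "gating"
        try:
            responsive = is_visually_responsive(gate.counts[ui], base.counts[ui])
            tuned = is_size_tuned(list(stim.counts[ui])) if responsive else False
            gated_in = bool(responsive and tuned and unit.layer in LAYERS)

            rate = stim.counts[ui].mean(axis=1) / T_s
            ff = np.array([fano_factor(stim.counts[ui, di]).ff
                           for di in range(diameters.size)])
            ff_sd = np.array([
                bootstrap_ff_sd(stim.counts[ui, di], B=config.B_err,
                                seed=_child_seed(config.seed, f"ffsd:{uid}:{di}"))
                for di in range(diameters.size)])
            base_counts_all = base.counts[ui].reshape(-1)
            ff_base = fano_factor(base_counts_all).ff
            base_rate = float(base_counts_all.mean() / 0.4)

            row = {"unit": uid, "penetration": unit.penetration, "channel": unit.channel,
                   "layer": unit.layer, "responsive": responsive, "size_tuned": tuned,
                   "gated_in": gated_in, "baseline_rate_hz": base_rate,
                   "baseline_ff": ff_base, "seed": config.seed}
            if not gated_in:
                rows.append(row)
                continue

            stage = "rate_tuning"
            rfit = fit_rate_rog(diameters, rate, n_restarts=config.rate_restarts,
                                seed=_child_seed(config.seed, f"rog:{uid}"))
            rf = rf_diameter(rfit)
            row["rf_deg"] = rf
            if rf is None:
                row["flags"] = "undefined_rf"
                rows.append(row)
                continue
            si = suppression_index(rfit, rf=rf)
            sur, sur_defined = surround_diameter(rfit, rf)
            row.update({"si": si, "surround_deg": sur, "surround_defined": sur_defined})

            stage = "variability"
            label = classify_unit_modulation(
                list(stim.counts[ui]), base_counts_all, unit_id=uid,
                B=config.B_classify, seed=_child_seed(config.seed, f"cls:{uid}"))
            row["unit_class"] = label.unit_class
            census[unit.layer][label.unit_class] += 1

            stage = "ff_tuning"
            ffit = fit_double_rog(diameters, ff, n_restarts=config.double_restarts,
                                  seed=_child_seed(config.seed, f"dff:{uid}"))
            sizes, ff_norm, flags = canonical_size_values(ffit, rf, s_min)
            ff_at = {k: ff_norm[k] * _curve_at(ffit, rf) for k in ff_norm}
            ff_at_sur = float(_curve_at(ffit, min(sur, S_MAX_DEG)))
            for k, v in ff_norm.items():
                row[f"ff_norm_{k}"] = v
            row["flags"] = ";".join(flags)

            per_layer_changes[unit.layer]["rf_vs_baseline"].append(
                _pct(ff_base, ff_at["rf"]))
            per_layer_changes[unit.layer]["near_vs_rf"].append(
                _pct(ff_at["rf"], ff_at["2rf"]))
            per_layer_changes[unit.layer]["surround_vs_rf"].append(
                _pct(ff_at["rf"], ff_at_sur))
            per_layer_changes[unit.layer]["far_vs_rf"].append(
                _pct(ff_at["rf"], ff_at["26"]))
            per_layer_si[unit.layer].append(si)

            stage = "shared_variability"
            if uid in sv_fits:
                sfit = sv_fits[uid]
                sv_rf = float(_curve_at(sfit, rf))
                if abs(sv_rf) > 1e-9:
                    row["sv_rf"] = sv_rf
                    per_layer_sv[unit.layer]["near_vs_rf"].append(
                        _pct(sv_rf, float(_curve_at(sfit, min(2 * rf, S_MAX_DEG)))))
                    per_layer_sv[unit.layer]["far_vs_rf"].append(
                        _pct(sv_rf, float(_curve_at(sfit, S_MAX_DEG))))
            rows.append(row)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed on unit {uid}: {e}") from e

    table = pd.DataFrame(rows)

    layers_summary = {}
    for lay in LAYERS:
        n_gated = sum(1 for r in rows if r["layer"] == lay and r.get("gated_in"))
        block = {"n_gated": int(n_gated)}
        ff_block, si_vals = {}, np.asarray(per_layer_si[lay], dtype=float)
        for contrast in FF_CONTRASTS:
            kept = _filter_extreme(per_layer_changes[lay][contrast])
            ff_block[contrast] = _median_block(
                kept, config.B_median, config.B_err,
                _child_seed(config.seed, f"med:{lay}:{contrast}"))
        block["ff_pct_change"] = ff_block
        sv_block = {}
        for contrast in SV_CONTRASTS:
            kept = _filter_extreme(per_layer_sv[lay][contrast])
            sv_block[contrast] = _median_block(
                kept, config.B_median, config.B_err,
                _child_seed(config.seed, f"svmed:{lay}:{contrast}"))
        block["sv_pct_change"] = sv_block
        corr_block = {}
        for contrast in ("near_vs_rf", "surround_vs_rf", "far_vs_rf"):
            vals = np.asarray(per_layer_changes[lay][contrast], dtype=float)
            if vals.size >= 5 and si_vals.size == vals.size and np.ptp(si_vals) > 0 \
                    and np.ptp(vals) > 0:
                corr_block[contrast] = correlate_ff_change_with_si(vals, si_vals)
        block["ff_si_correlation"] = corr_block
        block["census"] = census[lay]
        layers_summary[lay] = block

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "analysis_window_ms": list(window),
        "n_units_total": int(len(session.units)),
        "n_units_gated": int(table["gated_in"].sum()) if "gated_in" in table else 0,
        "layers": layers_summary,
    }
    summary = _round(summary)

    if out_dir is not None:
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        table.to_csv(out_dir / "per_unit.csv", index=False, lineterminator="\n")
        config.to_yaml(out_dir / "run_config.yaml")
    return summary, table


def _filter_extreme(values) -> np.ndarray:
    """Drop % changes beyond the exclusion bound (near-zero denominators)."""
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v) & (np.abs(v) <= PCT_CHANGE_EXCLUSION)]


def _curve_at(fit, s: float) -> float:
    from .tuning import _eval
    return float(_eval(fit, np.array([s]))[0])


def _pct(a: float, b: float) -> float:
    return 100.0 * (b - a) / a if a != 0 else np.inf


def layer_sign_summary(summary: dict) -> dict:
    """The key laminar contrasts and whether each matches the generator's
    ground-truth sign pattern: SG far-surround FF and shared-variance
    increase, IG near-surround FF and shared-variance decrease, G-layer FF
    flat beyond the RF.  "Flat" means the layer's median % change lies within
    2.5 bootstrap standard errors of zero -- a calibrated reading of "no
    change" that scales with the layer's sample size.
    """
    checks = {
        "SG_ff_far": ("SG", "ff_pct_change", "far_vs_rf", 1),
        "SG_sv_far": ("SG", "sv_pct_change", "far_vs_rf", 1),
        "G_ff_far": ("G", "ff_pct_change", "far_vs_rf", 0),
        "IG_ff_near": ("IG", "ff_pct_change", "near_vs_rf", -1),
        "IG_sv_near": ("IG", "sv_pct_change", "near_vs_rf", -1),
    }
    out = {}
    for key, (lay, kind, contrast, expected) in checks.items():
        block = summary["layers"][lay][kind][contrast]
        med = block["median"]
        if med is None:
            ok = False
        elif expected == 0:
            sd = block.get("boot_sd")
            ok = sd is None or abs(med) <= 2.5 * sd
        else:
            ok = (med > 0) if expected > 0 else (med < 0)
        out[key] = {"median": med, "expected_sign": expected, "matches": bool(ok)}
    out["all_match"] = all(v["matches"] for k, v in out.items() if isinstance(v, dict))
    return out


def make_report(summary: dict) -> str:
    """Render per-layer tables of median % changes and the unit census."""
    for key in ("layers", "seed", "n_units_total"):
        if key not in summary:
            raise KeyError(f"summary missing required key {key!r}")
    lines = [f"Run seed {summary['seed']}  (config {summary['config_hash']})",
             f"Units: {summary['n_units_gated']}/{summary['n_units_total']} "
             "passed gating (responsive, size-tuned, layer-assigned)"]
    if summary["n_units_gated"] == 0:
        lines.append("No units passed gating: nothing to report.")
        return "\n".join(lines) + "\n"
    for lay, block in summary["layers"].items():
        lines.append("")
        lines.append(f"=== Layer {lay} (n = {block['n_gated']}) ===")
        lines.append(f"{'contrast':<18}{'median %':>10}{'boot sd':>10}{'p(two)':>10}{'n':>5}")
        for contrast, st in block["ff_pct_change"].items():
            med = "-" if st["median"] is None else f"{st['median']:.1f}"
            sd = "-" if st.get("boot_sd") is None else f"{st['boot_sd']:.1f}"
            p = "-" if st.get("p_two_sided") is None else f"{st['p_two_sided']:.4f}"
            lines.append(f"FF {contrast:<15}{med:>10}{sd:>10}{p:>10}{st['n']:>5}")
        for contrast, st in block["sv_pct_change"].items():
            med = "-" if st["median"] is None else f"{st['median']:.1f}"
            sd = "-" if st.get("boot_sd") is None else f"{st['boot_sd']:.1f}"
            p = "-" if st.get("p_two_sided") is None else f"{st['p_two_sided']:.4f}"
            lines.append(f"SV {contrast:<15}{med:>10}{sd:>10}{p:>10}{st['n']:>5}")
        cen = block["census"]
        lines.append(f"census: {cen['amplifier']} amplifier(s), "
                     f"{cen['quencher']} quencher(s), {cen['neither']} neither")

    # raw p-values are the primary report; BH-adjusted values are an extension
    labelled_p = []
    for lay, block in summary["layers"].items():
        for kind in ("ff_pct_change", "sv_pct_change"):
            for contrast, st in block[kind].items():
                if st.get("p_two_sided") is not None:
                    labelled_p.append((f"{lay} {kind[:2].upper()} {contrast}",
                                       st["p_two_sided"]))
    if labelled_p:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([p for _, p in labelled_p], method="fdr_bh")
        lines.append("")
        lines.append("Benjamini-Hochberg adjusted p-values (extension; raw p above):")
        for (lab, p), pa in zip(labelled_p, p_adj):
            lines.append(f"  {lab:<28} raw {p:.4f}  adj {pa:.4f}")
    return "\n".join(lines) + "\n"
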