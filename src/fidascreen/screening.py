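"""Hit calling and campaign evaluation for binder screens.

Two complementary decision rules are implemented, matching the two regimes
of binder screening:

* **Fixed threshold** -- a candidate is a hit when its mean apparent R_h
  exceeds the reference (indicator alone, or the preculture control for
  lysate screens) by a fraction theta, default 10%.  Robust when the
  complex is much larger than the free indicator.
* **Dunnett many-to-one test** -- one-way ANOVA followed by Dunnett's
  multiple-comparison test of every candidate group against the control
  group, one-sided (binding can only increase R_h), with family-wise error
  control.  Needed when the expected size change is comparable to or below
  the threshold; the trade-off is that with tight technical replicates even
  tiny shifts become significant, so significant hits with a small R_h
  change deserve skepticism.

The dilution-series report scores both rules against simulated ground truth
(false positives = non-binders called, false negatives = binders missed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import fitting
from .fitting import FitOptions
from .physics import InstrumentMethod

__all__ = [
    "call_hits_threshold",
    "call_hits_dunnett",
    "dilution_series_report",
    "thermostability_compare",
    "screen_campaign",
]

DEFAULT_THETA = 0.10
DEFAULT_ALPHA = 0.05


def call_hits_threshold(summaries: pd.DataFrame, reference_rh: float,
                        theta: float = DEFAULT_THETA) -> pd.DataFrame:
    """Fixed-threshold hit calls on per-sample R_h summaries.

    ``summaries`` needs columns binder_id, rh_mean, rh_sd, n (a
    dilution_factor column is carried through when present).  A candidate is
    a hit iff rh_mean >= (1 + theta) * reference_rh.  The caller chooses the
    reference: indicator alone for purified screens, the matched preculture
    for lysate screens -- it is never inferred.
    """
    if reference_rh <= 0:
        raise ValueError("reference_rh must be > 0")
    out = summaries.copy()
    out["reference_rh"] = reference_rh
    out["pct_change"] = 100.0 * (out["rh_mean"] / reference_rh - 1.0)
    out["hit_threshold"] = out["rh_mean"] >= (1.0 + theta) * reference_rh
    return out


def call_hits_dunnett(replicate_rh: dict[str, np.ndarray], control: str,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Dunnett many-to-one comparison of candidate groups against a control.

    ``replicate_rh`` maps group labels to replicate R_h arrays; ``control``
    names the reference group (e.g. the preculture).  Each group needs
    n >= 2 (a variance is required).  The alternative is one-sided greater,
    since complex formation can only increase R_h.  Returns one row per
    candidate group with the Dunnett-adjusted p-value and the hit call at
    family-wise level ``alpha``; the one-way ANOVA p-value over all groups
    is attached as ``DataFrame.attrs['anova_p']``.
    """
    if control not in replicate_rh:
        raise ValueError(f"control group {control!r} missing from replicate data")
    for name, vals in replicate_rh.items():
        if len(np.atleast_1d(vals)) < 2:
            raise ValueError(
                f"group {name!r} has n={len(np.atleast_1d(vals))}; Dunnett's "
                "test needs n >= 2 per group"
            )
    names = [k for k in replicate_rh if k != control]
    groups = [np.asarray(replicate_rh[k], dtype=float) for k in names]
    ctrl = np.asarray(replicate_rh[control], dtype=float)

    res = stats.dunnett(*groups, control=ctrl, alternative="greater")
    p_adj = np.asarray(res.pvalue, dtype=float)
    anova_p = float(stats.f_oneway(ctrl, *groups).pvalue)

    out = pd.DataFrame({
        "binder_id": names,
        "rh_mean": [g.mean() for g in groups],
        "rh_sd": [g.std(ddof=1) for g in groups],
        "n": [len(g) for g in groups],
        "reference_rh": ctrl.mean(),
        "p_adjusted": p_adj,
        "hit_statistical": p_adj < alpha,
    })
    out["pct_change"] = 100.0 * (out["rh_mean"] / ctrl.mean() - 1.0)
    out.attrs["anova_p"] = anova_p
    out.attrs["control_n"] = len(ctrl)
    return out


def dilution_series_report(screen: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """False-positive / false-negative tally per dilution and per rule.

    ``screen`` holds one row per binder x dilution with hit columns
    (hit_threshold and/or hit_statistical); ``truth`` maps binder_id to
    is_binder.  Raises when the screen mentions a binder absent from the
    truth record.
    """
    truth_map = dict(zip(truth["binder_id"], truth["is_binder"]))
    unknown = set(screen["binder_id"]) - set(truth_map)
    if unknown:
        raise ValueError(f"screen results reference binders missing from the "
                         f"truth record: {sorted(unknown)}")
    rules = [c for c in ("hit_threshold", "hit_statistical") if c in screen.columns]
    if not rules:
        raise ValueError("screen table carries no hit columns")
    rows = []
    for dilution, grp in screen.groupby("dilution_factor"):
        is_binder = grp["binder_id"].map(truth_map).to_numpy(dtype=bool)
        for rule in rules:
            hit = grp[rule].to_numpy(dtype=bool)
            fp = int(np.sum(hit & ~is_binder))
            fn = int(np.sum(~hit & is_binder))
            n_nb = int(np.sum(~is_binder))
            n_b = int(np.sum(is_binder))
            rows.append({
                "dilution_factor": dilution,
                "rule": rule.removeprefix("hit_"),
                "false_positives": fp,
                "false_negatives": fn,
                "n_binders": n_b,
                "n_nonbinders": n_nb,
                "fp_rate": fp / n_nb if n_nb else float("nan"),
                "fn_rate": fn / n_b if n_b else float("nan"),
            })
    return pd.DataFrame(rows)


def thermostability_compare(rh_before: float, rh_after: float,
                            reference_rh: float,
                            theta: float = DEFAULT_THETA) -> str:
    """Classify a binder's heat challenge (e.g. 5 min at 95 C) outcome.

    ``retained``: the size increase passes the threshold rule both before
    and after heating; ``lost``: passes before but not after (the binder is
    heat-labile, or the initial call was spurious); ``inconclusive``: the
    binder never passed to begin with.
    """
    cutoff = (1.0 + theta) * reference_rh
    before_hit = rh_before >= cutoff
    after_hit = rh_after >= cutoff
    if before_hit and after_hit:
        return "retained"
    if before_hit and not after_hit:
        return "lost"
    return "inconclusive"


def _rh_from_sheet(sheet: pd.DataFrame, traces: dict, method: InstrumentMethod,
                   options: FitOptions) -> pd.DataFrame:
    """Per-sample R_h: fit traces when present, else take the rh_nm column."""
    if "rh_nm" in sheet.columns:
        out = sheet.copy()
        out["tr_s"] = np.nan
        return out
    rows = []
    for _, row in sheet.iterrows():
        tg = traces[row["trace_path"]]
        fit = fitting.fit_single_species(tg, method, options)
        r = row.to_dict()
        r.update(rh_nm=fit.rh, tr_s=fit.retention_time,
                 snr=fit.snr, flags=";".join(sorted(fit.flags)))
        rows.append(r)
    return pd.DataFrame(rows)


def screen_campaign(sheet: pd.DataFrame, traces: dict,
                    method: InstrumentMethod | None = None,
                    options: FitOptions = FitOptions(),
                    theta: float = DEFAULT_THETA,
                    alpha: float = DEFAULT_ALPHA,
                    viscosity_correct: bool = True) -> pd.DataFrame:
    """Full campaign evaluation: fit, normalize, summarize, call hits.

    Fits every trace in the sample sheet (or consumes pre-fitted ``rh_nm``
    values), corrects lysate samples for viscosity using the buffer-only
    indicator retention time, and per dilution calls hits with both the
    threshold rule (reference = preculture mean at the same dilution) and
    the one-sided Dunnett test against the preculture replicates.

    Returns one row per binder x dilution with both calls.
    """
    method = method or InstrumentMethod()
    for role in ("buffer", "preculture"):
        if not (sheet["role"] == role).any():
            raise ValueError(f"sample sheet lacks required role {role!r}")
    fits = _rh_from_sheet(sheet, traces, method, options)

    trace_mode = "trace_path" in sheet.columns
    if trace_mode and viscosity_correct:
        buffer_tr = fits.loc[fits["role"] == "buffer", "tr_s"].mean()
        lysate_mask = fits["role"] != "buffer"
        factor = fits.loc[lysate_mask, "tr_s"] / buffer_tr
        fits.loc[lysate_mask, "rh_nm"] = fits.loc[lysate_mask, "rh_nm"] / factor
        fits.loc[lysate_mask, "viscosity_factor"] = factor

    results = []
    for dilution, grp in fits[fits["role"] != "buffer"].groupby("dilution_factor"):
        pc = grp.loc[grp["role"] == "preculture", "rh_nm"].to_numpy()
        groups = {"PC": pc}
        summaries = []
        for binder_id, g in grp[grp["role"] == "binder"].groupby("binder_id"):
            vals = g["rh_nm"].to_numpy()
            groups[binder_id] = vals
            summaries.append({
                "binder_id": binder_id,
                "rh_mean": vals.mean(),
                "rh_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "n": len(vals),
            })
        summ = pd.DataFrame(summaries)
        thr = call_hits_threshold(summ, reference_rh=float(pc.mean()), theta=theta)
        dun = call_hits_dunnett(groups, control="PC", alpha=alpha)
        merged = thr.merge(dun[["binder_id", "p_adjusted", "hit_statistical"]],
                           on="binder_id")
        merged["dilution_factor"] = dilution
        results.append(merged)
    return pd.concat(results, ignore_index=True)
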