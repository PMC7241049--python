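"""Readers, writers, configuration and run reporting.

All tabular artifacts are plain TSV/CSV with documented headers; nested
results are JSON; the run configuration is a single nested YAML file with a
global seed. Every writer has a paired reader that accepts its output
unchanged (round-trip property, enforced in the test-suite).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AssociationResult,
    DepthProfile,
    IncubationSeries,
    KineticFit,
    LandscapeResult,
    OtuTable,
    SamplingEvent,
    Site,
)

logger = logging.getLogger(__name__)

__all__ = [
    "write_sites", "read_sites",
    "write_profiles",
    "write_otu_table", "read_otu_table",
    "write_incubations", "read_incubations",
    "write_truth", "read_truth",
    "write_fits", "read_fits",
    "write_landscape",
    "load_config", "default_config", "config_hash",
    "report",
]


# -- sites -------------------------------------------------------------------

_SITE_SCALARS = ["altitude", "temperature", "ph", "doc", "ch4_stream",
                 "ch4_pore", "co2_stream", "co2_pore", "do_stream", "do_pore"]


def write_sites(sites: Sequence[Site], path) -> None:
    rows = []
    for s in sites:
        row = {"site_id": s.site_id}
        row.update({k: getattr(s, k) for k in _SITE_SCALARS})
        row.update({f"cover_{k}": v for k, v in s.land_cover.items()})
        row.update({f"ion_{k}": v for k, v in s.ion_conc.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[Site]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for _, r in df.iterrows():
        cover = {c[len("cover_"):]: float(r[c]) for c in df.columns
                 if c.startswith("cover_")}
        ions = {c[len("ion_"):]: float(r[c]) for c in df.columns
                if c.startswith("ion_")}
        sites.append(Site(site_id=str(r["site_id"]), land_cover=cover,
                          ion_conc=ions,
                          **{k: float(r[k]) for k in _SITE_SCALARS}))
    return sites


def write_profiles(profiles: Sequence[DepthProfile], path) -> None:
    rows = []
    for p in profiles:
        for i in range(len(p.depth)):
            rows.append({"site_id": p.site_id, "depth_cm": p.depth[i],
                         "ch4_uM": p.ch4[i], "co2_uM": p.co2[i],
                         "do_uM": p.do[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- OTU table ---------------------------------------------------------------

def write_otu_table(table: OtuTable, path) -> None:
    """TSV with rows = OTUs, per-site count columns, `taxonomy` and `is_mob`."""
    out = table.counts.T.copy()
    out.insert(0, "otu_id", out.index)
    out["taxonomy"] = table.taxonomy.loc[out.index]
    out["is_mob"] = table.is_mob.loc[out.index].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_otu_table(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    if df.empty:
        raise ValueError(f"{path}: empty OTU table")
    for col in ("otu_id", "taxonomy", "is_mob"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.set_index("otu_id")
    site_cols = [c for c in df.columns if c not in ("taxonomy", "is_mob")]
    counts = df[site_cols]
    for col in site_cols:
        for otu, val in counts[col].items():
            f = float(val)
            if f < 0:
                raise ValueError(f"{path}: negative count at OTU {otu}, site {col}")
            if f != int(f):
                raise ValueError(
                    f"{path}: non-integer count {val!r} at OTU {otu}, site {col}"
                )
    return OtuTable(
        counts=counts.astype(int).T,
        taxonomy=df["taxonomy"].astype(str),
        is_mob=df["is_mob"].astype(bool),
    )


# -- incubations -------------------------------------------------------------

def write_incubations(series: Sequence[IncubationSeries], series_path,
                      events_path) -> None:
    """Long-format concentration CSV plus the sampling-event ledger CSV."""
    rows, ev_rows = [], []
    for s in series:
        for analyte, vals in sorted(s.conc.items()):
            for t, v in zip(s.times, vals):
                rows.append({"chamber": s.chamber_id, "site": s.site_id,
                             "replicate": s.replicate, "is_blank": s.is_blank,
                             "sediment_area_m2": s.sediment_area,
                             "water_volume_ml": s.water_volume,
                             "time_h": t, "analyte": analyte, "value_uM": v})
        for ev in s.events:
            row = {"chamber": s.chamber_id, "time_h": ev.time_h,
                   "withdrawn_mL": ev.withdrawn_ml}
            row.update({f"repl_{a}": c for a, c in sorted(ev.repl_conc.items())})
            ev_rows.append(row)
    pd.DataFrame(rows).to_csv(series_path, index=False)
    pd.DataFrame(ev_rows).to_csv(events_path, index=False)


def read_incubations(series_path, events_path) -> list[IncubationSeries]:
    df = pd.read_csv(series_path)
    ev = pd.read_csv(events_path) if events_path is not None else pd.DataFrame()
    known = set(df["chamber"].unique())
    if not ev.empty:
        unknown = set(ev["chamber"].unique()) - known
        if unknown:
            raise ValueError(f"events reference unknown chambers: {sorted(unknown)}")
    out = []
    for chamber, g in df.groupby("chamber", sort=True):
        conc = {}
        times = None
        for analyte, ga in g.groupby("analyte"):
            ga = ga.sort_values("time_h")
            if times is None:
                times = ga["time_h"].values
            conc[analyte] = ga["value_uM"].values
        events = []
        if not ev.empty:
            for _, r in ev[ev["chamber"] == chamber].sort_values("time_h").iterrows():
                repl = {c[len("repl_"):]: float(r[c]) for c in ev.columns
                        if c.startswith("repl_") and pd.notna(r[c])}
                events.append(SamplingEvent(time_h=float(r["time_h"]),
                                            withdrawn_ml=float(r["withdrawn_mL"]),
                                            repl_conc=repl))
        first = g.iloc[0]
        out.append(IncubationSeries(
            chamber_id=str(chamber), site_id=str(first["site"]),
            replicate=int(first["replicate"]), is_blank=bool(first["is_blank"]),
            sediment_area=float(first["sediment_area_m2"]),
            water_volume=float(first["water_volume_ml"]),
            times=times, conc=conc, events=events,
        ))
    return out


# -- truth / fits / landscape ------------------------------------------------

def write_truth(truth, path) -> None:
    payload = {
        "v_max": truth.v_max, "k_s": truth.k_s, "archetype": truth.archetype,
        "mob_cluster": truth.mob_cluster, "cluster2_sites": truth.cluster2_sites,
        "gradient": truth.gradient, "noise": truth.noise,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fits(fits: Sequence[KineticFit], path) -> None:
    pd.DataFrame([{
        "site": f.site_id, "V_max": f.v_max, "K_S": f.k_s,
        "se_Vmax": f.se_vmax, "se_KS": f.se_ks, "rss": f.rss,
        "mode": f.mode, "n_points": f.n_points, "converged": f.converged,
    } for f in fits]).to_csv(path, sep="\t", index=False)


def read_fits(path) -> list[KineticFit]:
    df = pd.read_csv(path, sep="\t")
    return [KineticFit(site_id=str(r["site"]), v_max=float(r["V_max"]),
                       k_s=float(r["K_S"]), rss=float(r["rss"]),
                       se_vmax=float(r["se_Vmax"]), se_ks=float(r["se_KS"]),
                       converged=bool(r["converged"]), mode=str(r["mode"]),
                       n_points=int(r["n_points"]))
            for _, r in df.iterrows()]


def write_landscape(result: LandscapeResult, outdir, density_grid: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "peaks": result.peaks,
        "mob_clusters": {k: int(v) for k, v in result.mob_clusters.items()},
        "hull_members": {str(k): v for k, v in result.hull_members.items()},
        "overrepresentation": {
            str(k): df.round(6).to_dict(orient="index")
            for k, df in result.overrep.items()
        },
        "excluded_sites": result.excluded_sites,
    }
    (outdir / "landscape.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    if density_grid:
        pd.DataFrame(result.density,
                     index=np.round(result.grid_y, 6),
                     columns=np.round(result.grid_x, 6)).to_csv(
            outdir / "density_grid.tsv", sep="\t")


# -- configuration -----------------------------------------------------------

def default_config() -> dict:
    return {
        "seed": 0,
        "synth": {
            "n_sites": 14,
            "n_otus": 2000,
            "noise_cv": 0.05,
            "replicates": 3,
            "blanks": 3,
            "days": 4.0,
            "per_day": 2,
        },
        "kinetics": {"mode": "trajectory", "per_replicate": False},
        "landscape": {"k": 2, "cutoff": 0.5, "outlier_rule": 3.0,
                      "grid_n": 150, "n_starts": 20},
        "assoc": {"exclude": []},
    }


def load_config(path: Optional[str] = None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("config must define a seed")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


# -- report ------------------------------------------------------------------

def report(
    fits: Optional[Sequence[KineticFit]] = None,
    landscape: Optional[LandscapeResult] = None,
    associations: Optional[Sequence[AssociationResult]] = None,
) -> tuple[str, dict]:
    """Combine stage outputs into a human-readable summary and JSON payload.

    Missing stages are listed explicitly and produce a partial report.
    Deterministic: identical inputs give byte-identical JSON.
    """
    payload: dict = {"missing": []}
    lines = ["# streammox run summary", ""]
    if fits:
        payload["kinetics"] = {
            f.site_id: {"V_max": round(f.v_max, 6), "K_S": round(f.k_s, 6),
                        "converged": f.converged}
            for f in fits
        }
        lines.append("## Site kinetics (V_max nmol m-2 h-1, K_S uM)")
        for f in sorted(fits, key=lambda f: f.site_id):
            lines.append(f"  {f.site_id}: V_max={f.v_max:.3g} K_S={f.k_s:.3g}"
                         f"{'' if f.converged else '  [NOT CONVERGED]'}")
    else:
        payload["missing"].append("kinetics")
        lines.append("## Site kinetics: MISSING")
    lines.append("")
    if landscape is not None:
        counts = landscape.mob_clusters.value_counts().to_dict()
        clusters = sorted(c for c in counts if c != 0)
        payload["landscape"] = {
            "n_clusters": len(clusters),
            "cluster_sizes": {str(c): int(counts[c]) for c in clusters},
            "n_unassigned": int(counts.get(0, 0)),
            "n_peaks": len(landscape.peaks),
            "hull_sizes": {str(c): len(v)
                           for c, v in landscape.hull_members.items()},
            "excluded_sites": landscape.excluded_sites,
        }
        lines.append(f"## Landscape: {len(clusters)} MOB clusters "
                     f"(sizes {[counts[c] for c in clusters]}, "
                     f"{counts.get(0, 0)} unassigned), "
                     f"{len(landscape.peaks)} density peaks")
    else:
        payload["missing"].append("landscape")
        lines.append("## Landscape: MISSING")
    lines.append("")
    if associations:
        payload["associations"] = {
            f"{a.response}~{a.predictor}": {"slope": round(a.slope, 6),
                                            "r2": round(a.r2, 4),
                                            "p": round(a.p, 6), "n": a.n}
            for a in associations
        }
        lines.append("## Associations")
        for a in associations:
            lines.append(f"  {a.response} ~ {a.predictor}: r2={a.r2:.3f} "
                         f"p={a.p:.3g} n={a.n}")
    else:
        payload["missing"].append("associations")
        lines.append("## Associations: MISSING")
    if payload["missing"]:
        logger.warning("report missing stages: %s", payload["missing"])
    return "\n".join(lines) + "\n", payload
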