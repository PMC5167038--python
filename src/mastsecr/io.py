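"""Readers/writers for the trapping-data TSV dialect and the pipeline.

Files are UTF-8, tab-separated with a header row:

* trap table: ``site  trap_id  x  y`` (coordinates in planar metres,
  origin at each site's grid corner);
* capture table: ``session  animal_id  occasion  trap_id`` with
  optional ``sex`` and ``check_time`` columns; ``session`` is
  ``site-year-month`` and occasions are 1-based.  When a check_time
  column is present, evening records are filtered out by default
  (morning catches only).

A :class:`StudyBundle` holds the per-site trap arrays, the capture
table, the mast calendar (autumn years with heavy beech seed crops) and
optional seed-quadrat counts; :func:`run_pipeline` executes the full
analysis on a bundle: per sex, candidate SECR models fitted per site
and ranked by AICc, best-model session estimates expanded into overlap
statistics and the two space-use mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import TrapArray
from .glmm import assemble_records, fit_lmm
from .likelihood import CaptureSession, SecrModelSpec, build_mask
from .overlap import overlap_table
from .selection import aicc, akaike_weights, enumerate_models, fit_candidates

__all__ = ["StudyBundle", "read_bundle", "write_bundle", "run_pipeline",
           "bundle_from_scenario"]

logger = logging.getLogger(__name__)

_TRAP_COLS = ["site", "trap_id", "x", "y"]
_CAP_COLS = ["session", "animal_id", "occasion", "trap_id"]


@dataclass
class StudyBundle:
    """All inputs of one study: traps, captures, mast calendar, seeds."""

    traps: dict[str, TrapArray]
    captures: pd.DataFrame          # site, year, month, sex?, animal_id, occasion, trap_id
    mast_autumn_years: list[int]
    n_occasions: int = 5
    seed_quadrats: pd.DataFrame | None = None

    def sites(self) -> list[str]:
        return sorted(self.traps)

    def session_keys(self) -> list[tuple[str, int, int]]:
        keys = self.captures[["site", "year", "month"]].drop_duplicates()
        return sorted(map(tuple, keys.to_numpy()))

    def trap_nights(self) -> int:
        """Total trap-nights: traps x occasions summed over site-sessions."""
        return sum(self.traps[site].n_traps * self.n_occasions
                   for site, _, _ in self.session_keys())

    def sessions_for(self, site: str, sex: str | None = None,
                     ) -> list[CaptureSession]:
        """CaptureSessions of one site (one per year-month), optionally
        restricted to one sex's records."""
        df = self.captures[self.captures["site"] == site]
        if sex is not None:
            if "sex" not in df.columns:
                raise ValueError("capture table has no sex column")
            df = df[df["sex"] == sex]
        out = []
        for (year, month), grp in df.groupby(["year", "month"], sort=True):
            recs = tuple(
                (str(r.animal_id), int(r.occasion), str(r.trap_id))
                for r in grp.itertuples())
            out.append(CaptureSession(
                session_id=(site, int(year), int(month)),
                n_occasions=self.n_occasions, records=recs))
        return out


def _parse_session_label(label: str) -> tuple[str, int, int]:
    parts = str(label).rsplit("-", 2)
    if len(parts) != 3:
        raise ValueError(f"malformed session label {label!r}; "
                         "expected site-year-month")
    site, year, month = parts
    return site, int(year), int(month)


def read_bundle(trap_path: str | Path, capture_path: str | Path,
                config: dict | str | Path,
                keep_evening: bool = False) -> StudyBundle:
    """Read and validate a study bundle from TSV files plus a config.

    ``config`` is a mapping (or path to a YAML file) with keys
    ``mast_autumn_years`` (list of years) and ``n_occasions``; an
    optional ``seed_quadrat_path`` points to a seed-count TSV.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    traps_df = pd.read_csv(trap_path, sep="\t", dtype={"trap_id": str})
    missing = set(_TRAP_COLS) - set(traps_df.columns)
    if missing:
        raise ValueError(f"trap table missing columns {sorted(missing)}")
    traps = {str(site): TrapArray.from_dataframe(grp)
             for site, grp in traps_df.groupby("site")}

    caps = pd.read_csv(capture_path, sep="\t",
                       dtype={"animal_id": str, "trap_id": str})
    missing = set(_CAP_COLS) - set(caps.columns)
    if missing:
        raise ValueError(f"capture table missing columns {sorted(missing)}")
    caps = caps.reset_index(drop=True)
    caps["line_no"] = caps.index + 2        # header is line 1
    if "check_time" in caps.columns and not keep_evening:
        n_evening = int((caps["check_time"] == "evening").sum())
        if n_evening:
            logger.info("filtered %d evening capture records", n_evening)
        caps = caps[caps["check_time"] != "evening"]
    occ = pd.to_numeric(caps["occasion"], errors="coerce")
    bad = caps[occ.isna() | (occ != occ.round()) | (occ < 1)]
    if not bad.empty:
        raise ValueError(
            "malformed occasion at line(s) "
            f"{bad['line_no'].tolist()}: {bad['occasion'].tolist()}")
    caps["occasion"] = occ.astype(int)
    parsed = caps["session"].map(_parse_session_label)
    caps["site"] = parsed.map(lambda t: t[0])
    caps["year"] = parsed.map(lambda t: t[1])
    caps["month"] = parsed.map(lambda t: t[2])

    for row in caps.itertuples():
        site_traps = traps.get(row.site)
        if site_traps is None:
            raise ValueError(f"line {row.line_no}: unknown site {row.site!r}")
        if row.trap_id not in site_traps.trap_ids:
            raise ValueError(
                f"line {row.line_no}: unknown trap_id {row.trap_id!r} "
                f"at site {row.site!r}")
    key_cols = ["session", "animal_id", "occasion"]
    if "sex" in caps.columns:
        key_cols = ["session", "sex", "animal_id", "occasion"]
    dup = caps[caps.duplicated(key_cols, keep=False)]
    if not dup.empty:
        offenders = dup.sort_values("line_no")[key_cols + ["line_no"]]
        raise ValueError(
            "duplicate (animal, occasion) records (an animal occupies one "
            f"trap per occasion):\n{offenders.to_string(index=False)}")

    seed_df = None
    if config.get("seed_quadrat_path"):
        seed_df = pd.read_csv(config["seed_quadrat_path"], sep="\t")
    keep = ["site", "year", "month", "animal_id", "occasion", "trap_id"]
    if "sex" in caps.columns:
        keep.insert(3, "sex")
    return StudyBundle(traps=traps, captures=caps[keep].reset_index(drop=True),
                       mast_autumn_years=list(config["mast_autumn_years"]),
                       n_occasions=int(config.get("n_occasions", 5)),
                       seed_quadrats=seed_df)


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to ``outdir`` (traps.tsv, captures.tsv, config.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trap_rows = []
    for site in bundle.sites():
        df = bundle.traps[site].to_dataframe()
        df.insert(0, "site", site)
        trap_rows.append(df)
    paths = {"traps": outdir / "traps.tsv",
             "captures": outdir / "captures.tsv",
             "config": outdir / "config.yaml"}
    pd.concat(trap_rows).to_csv(paths["traps"], sep="\t", index=False)
    caps = bundle.captures.copy()
    caps.insert(0, "session", caps["site"] + "-"
                + caps["year"].astype(str) + "-" + caps["month"].astype(str))
    cols = ["session", "animal_id", "occasion", "trap_id"]
    if "sex" in caps.columns:
        cols.append("sex")
    caps[cols].to_csv(paths["captures"], sep="\t", index=False)
    cfg = {"mast_autumn_years": [int(y) for y in bundle.mast_autumn_years],
           "n_occasions": int(bundle.n_occasions)}
    paths["config"].write_text(yaml.safe_dump(cfg), encoding="utf-8")
    if bundle.seed_quadrats is not None:
        paths["seeds"] = outdir / "seed_quadrats.tsv"
        bundle.seed_quadrats.to_csv(paths["seeds"], sep="\t", index=False)
    return paths


def bundle_from_scenario(sessions: dict, truth: pd.DataFrame,
                         traps: TrapArray,
                         mast_autumn_years: list[int],
                         n_occasions: int = 5) -> StudyBundle:
    """Assemble a StudyBundle from :func:`mastsecr.simulate.mast_cycle_scenario`
    output (the same trap grid is replicated at every site)."""
    rows = []
    for sex, site_sessions in sessions.items():
        for site, sess in site_sessions:
            _, year, month = sess.session_id
            for animal, occ, trap in sess.records:
                rows.append({"site": site, "year": year, "month": month,
                             "sex": sex, "animal_id": f"{sex[0]}{animal}",
                             "occasion": occ, "trap_id": trap})
    caps = pd.DataFrame(rows, columns=["site", "year", "month", "sex",
                                       "animal_id", "occasion", "trap_id"])
    site_names = sorted(truth["site"].unique())
    return StudyBundle(traps={s: traps for s in site_names}, captures=caps,
                       mast_autumn_years=mast_autumn_years,
                       n_occasions=n_occasions)


def run_pipeline(bundle: StudyBundle, outdir: str | Path,
                 specs: list[SecrModelSpec] | None = None,
                 buffer: float = 100.0, mask_spacing: float = 10.0,
                 sexes: tuple[str, ...] = ("female", "male"),
                 ) -> dict[str, Path]:
    """Run the full analysis chain on a bundle; writes TSV artifacts.

    Per sex: every candidate model is fitted independently per site
    (site-specific parameters throughout) and ranked by pooled AICc;
    the best structure's per-session (D, sigma) estimates feed the
    overlap statistics and the two space-use mixed models.  Outputs per
    sex a model table and a fits TSV, plus one overlap TSV and two
    GLMM term-test TSVs and a run log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = enumerate_models(specs)
    log_lines = [f"sites: {bundle.sites()}",
                 f"sessions: {len(bundle.session_keys())}",
                 f"trap nights: {bundle.trap_nights()}",
                 f"mast autumn years: {bundle.mast_autumn_years}",
                 f"candidate models: {len(specs)}",
                 f"buffer: {buffer} m, mask spacing: {mask_spacing} m"]
    artifacts: dict[str, Path] = {}
    best_fits = []   # (site, sex, SecrResults) of the best structure per sex
    for sex in sexes:
        stage = f"fit[{sex}]"
        try:
            per_spec = []
            site_fits: dict[int, list] = {i: [] for i in range(len(specs))}
            for site in bundle.sites():
                sessions = bundle.sessions_for(site, sex=sex)
                sessions = [s for s in sessions if s.n_individuals > 0]
                if not sessions:
                    logger.warning("%s: site %s has no captures; skipped",
                                   stage, site)
                    continue
                mask = build_mask(bundle.traps[site], buffer=buffer,
                                  spacing=mask_spacing)
                for i_spec, fit in enumerate(fit_candidates(
                        sessions, bundle.traps[site], mask, specs)):
                    site_fits[i_spec].append((site, fit))
            for i_spec, spec in enumerate(specs):
                fits = site_fits[i_spec]
                loglik = sum(f.loglik for _, f in fits)
                K = sum(f.k_params for _, f in fits)
                n = sum(f.n_individuals for _, f in fits)
                per_spec.append({
                    "lambda0": spec.lambda0_struct
                    + (" + behavioral" if spec.behavioral else ""),
                    "D": spec.d_struct, "sigma": spec.sigma_struct,
                    "K_params": K, "n": n, "loglik": loglik,
                    "AICc": aicc(loglik, K, n), "_spec": i_spec,
                    "converged": all(f.converged for _, f in fits)})
            table = pd.DataFrame(per_spec).sort_values(
                ["AICc", "K_params"]).reset_index(drop=True)
            table["deltaAICc"] = table["AICc"] - table["AICc"].iloc[0]
            table["weight"] = akaike_weights(table["AICc"].to_numpy())
            best_idx = int(table["_spec"].iloc[0])
            path = outdir / f"model_table_{sex}.tsv"
            table.drop(columns="_spec").to_csv(path, sep="\t", index=False)
            artifacts[f"model_table_{sex}"] = path
            log_lines.append(
                f"{stage}: best structure "
                f"{specs[best_idx].label()} (of {len(specs)})")
            fits_rows = []
            for site, fit in site_fits[best_idx]:
                # candidate fits skip the Hessian; redo it at the optimum
                fit = fit.model.fit(start_params=fit.params)
                best_fits.append((site, sex, fit))
                df = fit.conf_int() if fit.converged else fit.estimates()
                df.insert(0, "sex", sex)
                df.insert(0, "site", site)
                fits_rows.append(df)
            path = outdir / f"fits_{sex}.tsv"
            pd.concat(fits_rows).to_csv(path, sep="\t", index=False)
            artifacts[f"fits_{sex}"] = path
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage} failed: {err}") from err

    try:
        records = assemble_records(best_fits, bundle.mast_autumn_years)
        records = records.rename(columns={"D_hat": "D", "sigma_hat": "sigma"})
        records["session"] = list(zip(records["site"], records["year"],
                                      records["month"]))
        stats = overlap_table(records)
        path = outdir / "overlap.tsv"
        per = stats.per_session.drop(columns="session")
        per.to_csv(path, sep="\t", index=False)
        artifacts["overlap"] = path
    except Exception as err:
        raise RuntimeError(f"pipeline stage overlap failed: {err}") from err

    glmm_records = records.rename(columns={"D": "D_hat", "sigma": "sigma_hat"})
    for formula_id in ("density_model", "sigma_model"):
        stage = f"glmm[{formula_id}]"
        try:
            res = fit_lmm(glmm_records, formula_id)
            path = outdir / f"glmm_{formula_id}.tsv"
            res.anova().to_csv(path, sep="\t", index=False)
            artifacts[f"glmm_{formula_id}"] = path
            log_lines.append(f"{stage}: site var {res.group_var:.4g}"
                             + (" (boundary)" if res.boundary else ""))
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage} failed: {err}") from err

    import mastsecr
    log_lines.append(f"mastsecr version: {mastsecr.__version__}")
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    artifacts["run_log"] = log_path
    return artifacts
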