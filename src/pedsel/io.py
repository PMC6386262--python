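"""File formats, run configuration, and the end-to-end pipeline.

CSV dialect is fixed: comma-separated, UTF-8, ISO-8601 dates, period
decimal separator.  Pedigree files carry
``animal_id,sire_id,dam_id,sex,breed,birth_date`` (empty or "0" = unknown
parent); phenotype files carry ``animal_id,eval_date,age_days,hes,di``
plus any extra columns, with empty cells meaning missing.  An optional
``column_map`` lets externally named files (e.g. a supplementary-data
dictionary) be mapped onto this schema at read time.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pedsel.pedigree import Pedigree, PedigreeRecord, normalize_parent, topo_sort

logger = logging.getLogger("pedsel")

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "breed", "birth_date"]
PHENOTYPE_COLUMNS = ["animal_id", "eval_date", "age_days", "hes", "di"]

_SEX_MAP = {"m": "male", "male": "male", "f": "female", "female": "female",
            "": "unknown", "u": "unknown", "unknown": "unknown"}


def read_pedigree(path, column_map: dict | None = None) -> list[PedigreeRecord]:
    """Read a pedigree CSV into records (not yet sorted/validated).

    Raises with the offending row number on a missing column, duplicate
    animal id, unknown sex code, or unparseable date.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree column(s) {missing}")
    seen: set[str] = set()
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        aid = str(row.animal_id).strip()
        if not aid:
            raise ValueError(f"{path}:{rownum}: empty animal_id")
        if aid in seen:
            raise ValueError(f"{path}:{rownum}: duplicate animal_id {aid!r}")
        seen.add(aid)
        sex_raw = str(row.sex).strip().lower()
        if sex_raw not in _SEX_MAP:
            raise ValueError(f"{path}:{rownum}: unknown sex code {row.sex!r}")
        bd_raw = str(row.birth_date).strip()
        birth = None
        if bd_raw:
            try:
                birth = _dt.date.fromisoformat(bd_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{rownum}: bad birth_date {bd_raw!r}") from exc
        records.append(PedigreeRecord(
            aid, normalize_parent(row.sire_id), normalize_parent(row.dam_id),
            _SEX_MAP[sex_raw], str(row.breed).strip(), birth,
        ))
    return records


def write_pedigree(ped: Pedigree, path) -> None:
    rows = [{
        "animal_id": r.animal_id,
        "sire_id": r.sire_id or "",
        "dam_id": r.dam_id or "",
        "sex": r.sex,
        "breed": r.breed,
        "birth_date": r.birth_date.isoformat() if r.birth_date else "",
    } for r in ped.records]
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, index=False)


def read_phenotypes(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a phenotype CSV; validates HES range and drops all-missing rows."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype column(s) {missing}")
    df["hes"] = pd.to_numeric(df["hes"], errors="coerce")
    bad = df["hes"].notna() & ~df["hes"].isin(range(1, 9))
    if bad.any():
        rownum = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}:{rownum}: hes={df.loc[bad, 'hes'].iloc[0]} outside 1..8")
    df["hes"] = df["hes"].astype("Int64")
    df["di"] = pd.to_numeric(df["di"], errors="coerce")
    df["eval_date"] = pd.to_datetime(df["eval_date"], errors="coerce")
    both_missing = df["hes"].isna() & df["di"].isna()
    if both_missing.any():
        warnings.warn(f"dropped {int(both_missing.sum())} row(s) with neither HES nor DI")
        df = df.loc[~both_missing].reset_index(drop=True)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    pedigree: str = ""
    phenotypes: str = ""
    outdir: str = "pedsel_out"
    method: str = "reml"                  # "reml" | "gibbs" | "both"
    reml_tol: float = 1e-6
    reml_max_rounds: int = 200
    chain_iterations: int = 50_000
    chain_burn_in: int = 5_000
    chain_thin: int = 50
    quantile_method: str = "linear"
    gen_rounding: str = "half_up"
    seed: int = 0
    log_level: str = "INFO"
    hes_class_effects: tuple[str, ...] = ("sex", "cg", "gen_class")
    hes_covariates: tuple[str, ...] = ("age_days", "F_pct")
    di_class_effects: tuple[str, ...] = ("sex", "gen_class")
    di_covariates: tuple[str, ...] = ("F_pct",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for k in ("hes_class_effects", "hes_covariates", "di_class_effects", "di_covariates"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _prepare(cfg: RunConfig):
    """Load inputs and attach pedigree-derived columns to the phenotypes."""
    from pedsel.phenotypes import contemporary_groups

    ped = topo_sort(read_pedigree(cfg.pedigree))
    df = read_phenotypes(cfg.phenotypes)
    unknown = set(df["animal_id"]) - set(ped.ids)
    if unknown:
        raise ValueError(f"phenotyped animals missing from pedigree: {sorted(unknown)[:5]}")
    g, gen_class = ped.generation_coefficients(cfg.gen_rounding)
    F = ped.inbreeding()
    ix = df["animal_id"].map(ped.index)
    df = df.copy()
    df["gen_class"] = gen_class[ix]
    df["F_pct"] = 100.0 * F[ix]
    if "sex" not in df.columns:
        df["sex"] = [ped.records[i].sex for i in ix]
    if "breed" not in df.columns:
        df["breed"] = [ped.records[i].breed for i in ix]
    df["cg"] = contemporary_groups(df["eval_date"], df["breed"]).astype(str)
    return ped, df


def run_pipeline(cfg: RunConfig) -> dict:
    """Pedigree -> phenotype prep -> fit -> EBVs -> response tables -> trend tests.

    Writes a result bundle under ``cfg.outdir`` and returns the paths plus
    the in-memory reports.  Any stage failure raises with a stage-tagged
    message.
    """
    from pedsel.model import AnimalModel, ChainConfig, TraitSpec
    from pedsel.phenotypes import generation_summary, hesc_generation_table
    from pedsel.response import response_grid, response_table
    from pedsel.trend import jonckheere_terpstra, pearson_with_ci

    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(out)}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        stage("prepare")
        ped, df = _prepare(cfg)
    except Exception as exc:
        raise RuntimeError(f"[prepare] {exc}") from exc

    try:
        stage("summaries")
        hesc_generation_table(df["hes"], df["gen_class"]).to_csv(
            out / "table_hesc_by_generation.csv", index=False)
        generation_summary(df["di"], df["gen_class"], cfg.quantile_method).to_csv(
            out / "table_di_by_generation.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[summaries] {exc}") from exc

    try:
        stage("fit")
        specs = [
            TraitSpec("HES", "hes", cfg.hes_class_effects, cfg.hes_covariates),
            TraitSpec("DI", "di", cfg.di_class_effects, cfg.di_covariates),
        ]
        am = AnimalModel(df, ped, specs, drop_aliased=True)
        reports = {}
        fits = {}
        if cfg.method in ("reml", "both"):
            res = am.fit_reml(tol=cfg.reml_tol, max_rounds=cfg.reml_max_rounds)
            fits["reml"] = res
            reports["reml"] = res.to_report()
        if cfg.method in ("gibbs", "both"):
            chain = ChainConfig(cfg.chain_iterations, cfg.chain_burn_in, cfg.chain_thin)
            res = am.fit_gibbs(chain=chain, seed=cfg.seed)
            fits["gibbs"] = res
            reports["gibbs"] = res.to_report()
        if cfg.method == "both":
            reports["cross_method"] = {
                "h2_discrepancy": (np.asarray(reports["reml"]["h2"])
                                   - np.asarray(reports["gibbs"]["h2"])).tolist(),
                "r_a_discrepancy": reports["reml"]["r_a"] - reports["gibbs"]["r_a"],
            }
        (out / "variance_components.json").write_text(json.dumps(reports, indent=2))
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc

    try:
        stage("ebv")
        primary = fits.get("reml") or fits["gibbs"]
        ebv_long = primary.ebv_table.melt(
            id_vars="animal_id", var_name="trait", value_name="ebv")
        ebv_long["trait"] = ebv_long["trait"].str.replace("ebv_", "", regex=False)
        ebv_long.to_csv(out / "ebv.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[ebv] {exc}") from exc

    try:
        stage("response")
        rows = []
        for meth, rep in reports.items():
            if meth not in ("reml", "gibbs"):
                continue
            rows.append({
                "method": meth, "h2_x": rep["h2"][0], "r_a": rep["r_a"],
                "var_a_y": rep["G0"][1][1],
            })
        response_grid(pd.DataFrame(rows)).to_csv(out / "table_correlated_response.csv",
                                                 index=False)
        parents = set(ped.ids[i] for i in np.concatenate([ped.sire, ped.dam]) if i >= 0)
        resp_tab = response_table(
            df["di"], df["gen_class"], df["animal_id"].isin(parents))
        resp_tab.to_csv(out / "table_selection_differentials.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[response] {exc}") from exc

    try:
        stage("trend")
        sub = df.dropna(subset=["hes"])
        jt = jonckheere_terpstra(sub["hes"], sub["gen_class"], alternative="increasing")
        both = df.dropna(subset=["hes", "di"])
        r, lo, hi = pearson_with_ci(both["hes"], both["di"])
        trend = {
            "jt": {"statistic": jt.statistic, "z": jt.z, "p": jt.pvalue, "n": jt.n,
                   "alternative": jt.alternative},
            "pearson_hes_di": {"r": r, "ci": [lo, hi], "n": int(len(both))},
        }
        (out / "trend_tests.json").write_text(json.dumps(trend, indent=2))
    except Exception as exc:
        raise RuntimeError(f"[trend] {exc}") from exc

    import pedsel

    log = {
        "package_version": pedsel.__version__,
        "numpy": np.__version__,
        "seed": cfg.seed,
        "method": cfg.method,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "n_records": int(len(df)),
        "n_pedigree": len(ped),
        "convergence": {m: reports[m].get("rounds", reports[m].get("chain"))
                        for m in reports if m in ("reml", "gibbs")},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["reports"] = reports
    bundle["trend"] = trend
    bundle["files"] = sorted(p.name for p in out.iterdir())
    return bundle
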