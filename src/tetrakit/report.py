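"""Analysis driver: runs the full tetrad pipeline over one dissection
dataset and writes the standard report tables (map distances, aberrant
segregation, coefficient of coincidence, NPD ratios, viability).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import TetradDataset, aberrant_rate, read_tetrad_table
from .interference import (
    ModelInfeasibleError,
    coc_test,
    count_dco,
    expected_dco,
    npd_ratio_test,
)
from .linkage import (
    EXCLUDED,
    classify_interval,
    perkins_distance,
    spore_rf,
    spore_tally,
    tally_interval,
)
from .strain_stats import ndj_signature, viability_profile

log = logging.getLogger("tetrakit")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the published tables
    (Python's built-in round is banker's rounding)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass
class AnalysisConfig:
    dataset_path: str
    map_path: str
    intervals: list[tuple[str, str]]
    interval_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    npd_method: str = "mle"
    confidence: float = 0.95
    viability_cutoff: float = 50.0
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["intervals"] = [tuple(iv) for iv in raw["intervals"]]
        raw["interval_pairs"] = [tuple(p) for p in raw.get("interval_pairs", [])]
        cfg = cls(**raw)
        for p in (cfg.dataset_path, cfg.map_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def map_distance_table(
    dataset: TetradDataset, intervals: list[tuple[str, str]], confidence: float = 0.95
) -> pd.DataFrame:
    """Per-interval spore and tetrad map estimates (published-table layout)."""
    rows = []
    for a, b in intervals:
        st = spore_tally(dataset, (a, b))
        sp = spore_rf(st, confidence)
        ta = tally_interval(dataset, (a, b))
        te = perkins_distance(ta)
        rows.append(
            {
                "interval": f"{a}-{b}",
                "chromosome": dataset.marker_map[a].chromosome,
                "spores_n": st.total,
                "parental": st.parental,
                "recombinant": st.recombinant,
                "spore_cM": round_half_up(sp.cM),
                "ci_low": round_half_up(sp.ci_cM[0]),
                "ci_high": round_half_up(sp.ci_cM[1]),
                "tetrads_N": ta.n,
                "PD": ta.pd,
                "TT": ta.tt,
                "NPD": ta.npd,
                "tetrad_cM": round_half_up(te.cM),
                "SE": round_half_up(te.se_cM),
            }
        )
    return pd.DataFrame(rows)


def aberrant_table(dataset: TetradDataset) -> pd.DataFrame:
    rows = []
    for m in dataset.marker_map:
        rows.append(
            {
                "marker": m.name,
                "chromosome": m.chromosome,
                "aberrant_pct": round_half_up(aberrant_rate(dataset, m.name)),
            }
        )
    return pd.DataFrame(rows)


def coc_table(
    dataset: TetradDataset, interval_pairs: list[tuple[str, str, str]]
) -> pd.DataFrame:
    rows = []
    for a, b, c in interval_pairs:
        t1 = tally_interval(dataset, (a, b))
        t2 = tally_interval(dataset, (b, c))
        obs = count_dco(dataset, (a, b), (b, c))
        exp = expected_dco(t1, t2)
        res = coc_test(obs, exp, t1.n)
        rows.append(
            {
                "interval_pair": f"{a}-{b}-{c}",
                "tetrads_N": t1.n,
                "dco_obs": obs,
                "dco_exp": round_half_up(exp),
                "coc": round_half_up(res.coc, 3),
                "p_value": res.p_two_tailed,
                "interference": "YES" if res.interference_called else "NO",
            }
        )
    return pd.DataFrame(rows)


def npd_table(
    dataset: TetradDataset,
    intervals: list[tuple[str, str]],
    method: str = "mle",
) -> pd.DataFrame:
    rows = []
    for a, b in intervals:
        tally = tally_interval(dataset, (a, b))
        try:
            res = npd_ratio_test(tally, method=method)
        except ModelInfeasibleError:
            log.warning("interval %s-%s infeasible for NPD-ratio test", a, b)
            continue
        rows.append(
            {
                "interval": f"{a}-{b}",
                "tetrads_N": tally.n,
                "npd_obs": tally.npd,
                "npd_exp": round_half_up(res.npd_exp, 2),
                "ratio": round_half_up(res.ratio, 3),
                "x_hat": round_half_up(res.x_hat, 4),
                "chi2": round_half_up(res.chi2, 2),
                "p_value": res.p,
                "interference": "YES" if res.interference_called else "NO",
            }
        )
    return pd.DataFrame(rows)


def viability_table(dataset: TetradDataset) -> pd.DataFrame:
    prof = viability_profile(dataset)
    row = {
        "strain": dataset.strain,
        "n_tetrads": len(dataset),
        "percent_viable": round_half_up(prof.percent_viable),
    }
    for k in range(4, -1, -1):
        row[f"viable_{k}"] = prof.counts_by_viable_spores[k]
    try:
        sig = ndj_signature(dataset)
        row["two_spore_tetrads"] = sig.two_spore_tetrads
        row["nonmater_pct"] = round_half_up(sig.nonmater_two_spore_fraction)
        row["sister_pct"] = round_half_up(sig.sister_two_spore_fraction)
    except Exception:  # no mating-type marker configured
        pass
    return pd.DataFrame([row])


def run_analysis(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run every pipeline stage and write TSV reports into ``out_dir``.

    Returns the report tables keyed by stage name.  Stage errors propagate
    with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = read_tetrad_table(config.dataset_path, config.map_path)
    n_complete = sum(t.n_viable == 4 for t in dataset.tetrads)
    log.info(
        "loaded %d tetrads (%d four-spore viable) from %s",
        len(dataset),
        n_complete,
        config.dataset_path,
    )
    for a, b in config.intervals:
        excl = sum(
            classify_interval(t, dataset.marker_map, (a, b)) == EXCLUDED
            for t in dataset.tetrads
        )
        log.info("interval %s-%s: %d tetrads excluded", a, b, excl)

    reports: dict[str, pd.DataFrame] = {}
    stages = [
        ("map_distances", lambda: map_distance_table(dataset, config.intervals, config.confidence)),
        ("aberrant_segregation", lambda: aberrant_table(dataset)),
        ("viability", lambda: viability_table(dataset)),
        ("npd_ratio", lambda: npd_table(dataset, config.intervals, config.npd_method)),
    ]
    if config.interval_pairs:
        stages.insert(2, ("coc", lambda: coc_table(dataset, config.interval_pairs)))
    for name, fn in stages:
        try:
            reports[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# tetrakit {__version__}  stage={name}\n")
            reports[name].to_csv(fh, sep="\t", index=False)
        log.info("wrote %s", path)
    return reports
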