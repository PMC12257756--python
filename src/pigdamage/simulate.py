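"""Synthetic pig populations with ear/tail damage phenotypes.

Generates discrete-generation pedigrees for several closed lines housed on a
set of farms (litters nested in dams, pens of 6-16 animals mixing
neighbouring litters, herd-year-season groups of birth and of scoring, a
scorer per pen) and bivariate phenotypes from Gaussian liabilities with
additive-genetic, litter, pen-group, herd-year-season and residual
components. In ordinal mode the liabilities are thresholded to 0-3 damage
scores; in gaussian mode the liabilities themselves are the phenotypes.

The generator exists because the real damage-score data are proprietary:
every downstream stage (REML, BLUP validation, selection response) is
exercised against simulated data with known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, read_pedigree
from .traits import derive_traits

TRAIT_AXES = ("ear", "tail")


@dataclass
class SimulationConfig:
    """Population structure and true parameter values for the generator.

    Variance-component defaults give each liability a total variance of 1.0
    with h^2 = 0.05, a litter fraction of 0.10, a pen fraction of 0.20 and a
    herd-year-season fraction of 0.10; the genetic correlation between the
    ear and tail liabilities defaults to 0.45. Litter sizes follow a clipped
    Poisson with mean 12.5 and pens hold 6-16 animals.
    """

    n_lines: int = 6
    n_farms: int = 13
    generations: int = 3          # generation 0 = founders (unphenotyped)
    sires_per_generation: int = 14   # per line
    dams_per_generation: int = 105   # per line
    litter_mean: float = 12.5
    litter_min: int = 1
    litter_max: int = 30
    # animals entering the testing station (phenotyped) per litter; the
    # remaining littermates are never scored and are left out of the
    # pedigree -- commercial nucleus data score only a few pigs per litter
    tested_per_litter: int = 4
    pen_size_range: tuple[int, int] = (6, 16)
    n_hys_birth: int = 60
    n_hys_scoring: int = 36
    n_scorers: int = 10
    age_range: tuple[int, int] = (130, 180)   # days at scoring

    # true variance components, identical for the ear and tail liabilities
    var_a: float = 0.05
    var_litter: float = 0.10
    var_pen: float = 0.20
    var_hys: float = 0.10
    var_e: float = 0.55

    # correlations between the ear and tail components
    r_genetic: float = 0.45
    r_litter: float = 0.30
    r_pen: float = 0.30
    r_hys: float = 0.30
    r_residual: float = 0.30

    phenotype_mode: str = "gaussian"          # "gaussian" | "ordinal"
    # liability cutpoints; defaults are the N(0,1) quantiles for marginal
    # score prevalences (0.75, 0.15, 0.07, 0.03)
    thresholds: tuple[float, float, float] = (0.6745, 1.2816, 1.8808)

    # fixed-effect generation: magnitudes echo effects seen in commercial
    # damage-score data (age slope ~ 0.001-0.002 score units per day)
    sex_effect: tuple[float, float] = (0.05, -0.05)   # (ear, tail) gilt-boar
    line_sd: float = 0.15
    sexline_sd: float = 0.05
    scorer_sd: float = 0.05
    age_slope: tuple[float, float] = (0.0012, 0.0012)

    seed: int = 0

    def validate(self) -> None:
        for name in ("var_a", "var_litter", "var_pen", "var_hys", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("r_genetic", "r_litter", "r_pen", "r_hys", "r_residual"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        lo, hi = self.pen_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pen size range")
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly increasing")
        if self.phenotype_mode not in ("gaussian", "ordinal"):
            raise ValueError("phenotype_mode must be 'gaussian' or 'ordinal'")
        if self.generations < 1:
            raise ValueError("need at least one generation")

    def component_covariances(self) -> dict[str, np.ndarray]:
        """2x2 true covariance matrix per random term (ear x tail)."""
        out = {}
        for term, v, r in [
            ("animal", self.var_a, self.r_genetic),
            ("litter", self.var_litter, self.r_litter),
            ("pen", self.var_pen, self.r_pen),
            ("hys_scoring", self.var_hys, self.r_hys),
            ("residual", self.var_e, self.r_residual),
        ]:
            cov = np.array([[v, r * v], [r * v, v]])
            if np.linalg.eigvalsh(cov).min() < -1e-12:
                raise ValueError(f"non-PSD covariance for term {term}")
            out[term] = cov
        return out

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("pen_size_range", "age_range", "thresholds",
                    "sex_effect", "age_slope"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulatedDataset:
    """A simulated population with its full generating truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame          # one row per phenotyped animal
    true_bv: pd.DataFrame             # animal x (ear, tail), whole pedigree
    true_effects: dict[str, pd.DataFrame]   # litter/pen/hys level x trait
    liabilities: pd.DataFrame         # phenotyped animal x (ear, tail)
    config: SimulationConfig


def simulate_pedigree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, pd.DataFrame]:
    """Simulate the pedigree and all group assignments.

    Returns the topologically ordered pedigree plus a per-animal table of
    line, farm, generation, sex, litter, pen, herd-year-season of birth and
    of scoring, scorer, age at scoring and birth date. Founders (generation
    0) have no group assignments and are not phenotyped.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    farms_of_line = {
        line: [f for f in range(cfg.n_farms) if f % cfg.n_lines == line]
        for line in range(cfg.n_lines)
    }
    hysb_levels = _allocate_levels(
        "hb", cfg.n_hys_birth, cfg.n_farms, cfg.generations)
    hyss_levels = _allocate_levels(
        "hs", cfg.n_hys_scoring, cfg.n_farms, cfg.generations)

    records: list[tuple[str, str | None, str | None]] = []
    rows: list[dict] = []

    def new_id(line: int, gen: int, k: int) -> str:
        return f"L{line}G{gen}N{k:05d}"

    for line in range(cfg.n_lines):
        males: list[str] = []
        females: list[str] = []
        counter = 0
        for k in range(cfg.sires_per_generation):
            a = new_id(line, 0, counter); counter += 1
            records.append((a, None, None))
            males.append(a)
            rows.append(_founder_row(a, line))
        for k in range(cfg.dams_per_generation):
            a = new_id(line, 0, counter); counter += 1
            records.append((a, None, None))
            females.append(a)
            rows.append(_founder_row(a, line))

        for gen in range(1, cfg.generations):
            sires = list(rng.choice(males, cfg.sires_per_generation,
                                    replace=False))
            dams = list(rng.choice(females, cfg.dams_per_generation,
                                   replace=False))
            males, females = [], []
            cohorts: dict[int, list[dict]] = {f: [] for f in farms_of_line[line]}
            for j, dam in enumerate(dams):
                sire = sires[rng.integers(len(sires))]
                farm = farms_of_line[line][j % len(farms_of_line[line])]
                litter_id = f"{dam}.g{gen}"
                hysb = _pick(rng, hysb_levels[(farm, gen)])
                born = int(np.clip(rng.poisson(cfg.litter_mean),
                                   cfg.litter_min, cfg.litter_max))
                size = min(born, cfg.tested_per_litter)
                first_sex = int(rng.integers(2))
                for k in range(size):
                    a = new_id(line, gen, counter); counter += 1
                    records.append((a, sire, dam))
                    sex = "boar" if (k + first_sex) % 2 == 0 else "gilt"
                    (males if sex == "boar" else females).append(a)
                    cohorts[farm].append({
                        "animal": a, "line": f"line{line}", "farm": farm,
                        "generation": gen, "sex": sex, "litter": litter_id,
                        "hys_birth": hysb,
                    })
            for farm, cohort in cohorts.items():
                if not cohort:
                    continue
                _assign_pens(cohort, cfg, rng, line, farm, gen,
                             hyss_levels[(farm, gen)])
                hysb_list = hysb_levels[(farm, gen)]
                for r in cohort:
                    season = hysb_list.index(r["hys_birth"]) % 4
                    r["age_days"] = int(
                        rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
                    r["birth_date"] = date(
                        2020 + gen, 1 + 3 * season,
                        int(rng.integers(1, 29))).isoformat()
                    r["phenotyped"] = True
                rows.extend(cohort)

    ped = Pedigree.from_records(records)
    groups = pd.DataFrame(rows).set_index("animal")
    groups = groups.loc[[a for a in ped.ids]]  # pedigree order
    return ped, groups


def _founder_row(animal: str, line: int) -> dict:
    return {
        "animal": animal, "line": f"line{line}", "farm": -1, "generation": 0,
        "sex": "", "litter": "", "hys_birth": "", "hys_scoring": "",
        "scorer": "", "pen": "", "age_days": 0, "birth_date": "",
        "phenotyped": False,
    }


def _allocate_levels(prefix: str, total: int, n_farms: int,
                     generations: int) -> dict[tuple[int, int], list[str]]:
    """Partition `total` labelled levels over (farm, generation) cells."""
    cells = [(f, g) for g in range(1, max(generations, 2))
             for f in range(n_farms)]
    out: dict[tuple[int, int], list[str]] = {c: [] for c in cells}
    for k in range(max(total, len(cells))):
        cell = cells[k % len(cells)]
        out[cell].append(f"{prefix}{k:04d}")
    return out


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _assign_pens(cohort: list[dict], cfg: SimulationConfig,
                 rng: np.random.Generator, line: int, farm: int,
                 gen: int, hyss_options: list[str]) -> None:
    """Cut a farm cohort into pens, mixing neighbouring litters.

    Litters are concatenated in random order and cut into pens of random
    size, so most pens contain animals from two or more litters while
    litters span about two pens -- the mixing pattern of group housing.
    """
    lo, hi = cfg.pen_size_range
    n = len(cohort)
    if n < lo:
        raise ValueError(
            f"infeasible pen constraints: cohort of {n} animals on farm "
            f"{farm} is smaller than the minimum pen size {lo}")
    litters: dict[str, list[dict]] = {}
    for r in cohort:
        litters.setdefault(r["litter"], []).append(r)
    order = list(litters)
    rng.shuffle(order)
    stream = [r for lid in order for r in litters[lid]]

    sizes: list[int] = []
    left = n
    while left >= lo:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, left)
        if left - size < lo and left - size > 0:
            # avoid an undersized remainder pen
            if left <= hi:
                size = left
            elif left - lo >= lo:
                size = left - lo
        sizes.append(size)
        left -= size
    if left > 0:
        # spread the remainder over existing pens without exceeding the max
        for k in range(left):
            j = k % len(sizes)
            if sizes[j] >= hi:
                raise ValueError("infeasible pen constraints: remainder "
                                 "cannot be distributed within pen sizes")
            sizes[j] += 1

    scorers = [f"scorer{t:02d}" for t in range(cfg.n_scorers)]
    pos = 0
    for p, size in enumerate(sizes):
        pen_id = f"pen_L{line}F{farm}G{gen}P{p:03d}"
        hyss = _pick(rng, hyss_options)
        scorer = _pick(rng, scorers)
        for r in stream[pos:pos + size]:
            r["pen"] = pen_id
            r["hys_scoring"] = hyss
            r["scorer"] = scorer
        pos += size


def simulate_phenotypes(
    ped: Pedigree,
    groups: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw breeding values, group effects and phenotypes for a pedigree.

    Breeding values follow the pedigree: founders are drawn from
    N(0, Sigma_a) and descendants as the parent average plus a Mendelian
    sampling deviation with covariance d_i * Sigma_a, where d_i carries the
    parental-inbreeding correction (d_i = 0.5 (1 - 0.5 (F_s + F_d)) when
    both parents are known). Litter, pen and herd-year-season effects are
    i.i.d. draws from their 2x2 covariances; the two liabilities are the
    fixed part plus the sum of the random terms. In ordinal mode each
    liability is cut at the three thresholds into a 0-3 damage score.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    covs = cfg.component_covariances()
    n = len(ped)

    # --- breeding values down the pedigree ------------------------------
    chol_a = _safe_chol(covs["animal"])
    d = ped.mendelian_d
    bv = np.zeros((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        m = (np.sqrt(d[i]) * z[i]) @ chol_a.T
        s, t = ped.sire[i], ped.dam[i]
        pa = np.zeros(2)
        if s >= 0:
            pa += 0.5 * bv[s]
        if t >= 0:
            pa += 0.5 * bv[t]
        bv[i] = pa + m
    true_bv = pd.DataFrame(bv, index=ped.ids, columns=list(TRAIT_AXES))

    # --- group effects ---------------------------------------------------
    pheno = groups[groups["phenotyped"] == True].copy()  # noqa: E712
    effects: dict[str, pd.DataFrame] = {}
    for term, col in [("litter", "litter"), ("pen", "pen"),
                      ("hys_scoring", "hys_scoring")]:
        levels = sorted(pheno[col].unique())
        draws = rng.standard_normal((len(levels), 2)) @ _safe_chol(covs[term]).T
        effects[term] = pd.DataFrame(draws, index=levels,
                                     columns=list(TRAIT_AXES))
    resid = rng.standard_normal((len(pheno), 2)) @ _safe_chol(covs["residual"]).T

    # --- fixed part ------------------------------------------------------
    lines = sorted(groups["line"].unique())
    line_eff = {ln: rng.normal(0.0, cfg.line_sd, 2) for ln in lines}
    sexline_eff = {(ln, sx): rng.normal(0.0, cfg.sexline_sd, 2)
                   for ln in lines for sx in ("boar", "gilt")}
    scorer_ids = sorted(pheno["scorer"].unique())
    scorer_eff = {sc: rng.normal(0.0, cfg.scorer_sd, 2) for sc in scorer_ids}

    sex_vec = np.array(cfg.sex_effect)
    slope = np.array(cfg.age_slope)
    age_centred = pheno["age_days"].to_numpy() - np.mean(cfg.age_range)
    fixed = np.zeros((len(pheno), 2))
    for k, (a, row) in enumerate(pheno.iterrows()):
        fixed[k] = (
            line_eff[row["line"]]
            + (sex_vec if row["sex"] == "gilt" else 0.0)
            + sexline_eff[(row["line"], row["sex"])]
            + scorer_eff[row["scorer"]]
            + slope * age_centred[k]
        )

    liab = (
        fixed
        + bv[[ped.index_of(a) for a in pheno.index]]
        + effects["litter"].loc[pheno["litter"]].to_numpy()
        + effects["pen"].loc[pheno["pen"]].to_numpy()
        + effects["hys_scoring"].loc[pheno["hys_scoring"]].to_numpy()
        + resid
    )
    liabilities = pd.DataFrame(liab, index=pheno.index,
                               columns=list(TRAIT_AXES))

    table = pheno.drop(columns=["phenotyped"]).reset_index()
    if cfg.phenotype_mode == "gaussian":
        table["ear"] = liab[:, 0]
        table["tail"] = liab[:, 1]
    else:
        cuts = np.array(cfg.thresholds)
        table["ED03"] = np.digitize(liab[:, 0], cuts)
        table["TD03"] = np.digitize(liab[:, 1], cuts)
        table = derive_traits(table)

    return SimulatedDataset(
        pedigree=ped,
        phenotypes=table,
        true_bv=true_bv,
        true_effects=effects,
        liabilities=liabilities,
        config=cfg,
    )


def _safe_chol(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerating zero variance / unit correlation."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate pedigree, groups and phenotypes from a single RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    ped, groups = simulate_pedigree(cfg, rng)
    return simulate_phenotypes(ped, groups, cfg, rng)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write pedigree, phenotype, truth and config files to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.pedigree.to_frame().to_csv(outdir / "pedigree.csv", index=False)
    ds.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    truth = ds.true_bv.loc[ds.phenotypes["animal"]].reset_index()
    truth = truth.melt(id_vars="index", var_name="trait",
                       value_name="true_bv")
    truth = truth.rename(columns={"index": "animal"})
    truth.to_csv(outdir / "truth.csv", index=False)
    ds.config.to_yaml(outdir / "config.yaml")


def read_dataset(outdir) -> tuple[Pedigree, pd.DataFrame, pd.DataFrame]:
    """Read back (pedigree, phenotypes, truth) written by write_dataset."""
    outdir = Path(outdir)
    ped = read_pedigree(outdir / "pedigree.csv")
    pheno = pd.read_csv(outdir / "phenotypes.csv")
    truth = pd.read_csv(outdir / "truth.csv")
    return ped, pheno, truth
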