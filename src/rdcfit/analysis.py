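"""Integrated analyses on top of the SVD solver.

* Monte Carlo sampling of the solution space: the observations are resampled
  within their error bars, each perturbed system is refit, and a trial tensor
  is kept only if it satisfies every *unperturbed* observation within error.
  The best-fit (unperturbed least-squares) tensor is always the first entry.
* Per-equation rejection/error analysis: residuals, violation flags, RMSD and
  Q-factor, and greedy iterative rejection of violating equations — the
  localized structure-validation workflow.
* Full reports aggregating all of the above per alignment medium, and
  ensemble analysis ranking many data files by fitness.

A "violation" is a residual strictly greater than the equation's error plus a
1e-9 Hz numerical slack (so exactly-fitting data with zero error bars are not
flagged by float rounding).  Monte Carlo acceptance uses the same rule, which
makes acceptance counts exactly recountable from the stored tensors.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np

from .core import RDCSet, SaupeTensor, back_calculate
from .svd import EmptySystemError, SvdSolution, build_system, solve
from .projections import SFPoint, sf_plot_data
from .tensor import anisotropy, diagonalize

__all__ = [
    "SolutionEnsemble", "ErrorReport", "MediumReport", "FullReport",
    "ValidationResult", "EnsembleResult",
    "monte_carlo_solutions", "error_analysis", "q_factor",
    "iterative_rejection", "localized_validation", "full_report",
    "ensemble_analysis", "satisfies_within_error",
]

#: Absolute numerical slack (Hz) on the within-error test.
VIOLATION_ATOL = 1e-9

#: Pairs whose axial anisotropy Da is tabulated in reports.
REPORT_PAIRS = ("C-N", "N-H", "C-H", "H-H")


def _with_errors(rdcs: RDCSet, error_threshold: float | None) -> RDCSet:
    """Replace every per-row error with a uniform threshold, if given."""
    if error_threshold is None:
        return rdcs
    from dataclasses import replace

    data = [replace(d, error=float(error_threshold)) for d in rdcs.data]
    return RDCSet(data=data, selection=rdcs.selection.copy(),
                  medium_label=rdcs.medium_label)


def satisfies_within_error(tensor: SaupeTensor, rdcs: RDCSet) -> bool:
    """True iff every selected, observed equation is reproduced within error."""
    for d in rdcs.usable():
        if abs(back_calculate(tensor, d) - d.d_obs) > d.error + VIOLATION_ATOL:
            return False
    return True


@dataclass
class SolutionEnsemble:
    best: SvdSolution  # least-squares solution, always entry one
    accepted: list[SaupeTensor]  # Monte Carlo tensors satisfying all data
    n_trials: int
    n_within_error: int
    seed: int


def monte_carlo_solutions(rdcs: RDCSet, n_trials: int, seed: int) -> SolutionEnsemble:
    """Sample the within-error solution space around the least-squares fit.

    Per trial each selected observation is perturbed by an independent
    uniform draw in [-error, +error]; the perturbed system is refit and the
    trial tensor accepted iff it back-calculates every unperturbed
    observation within its error.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    best = solve(build_system(rdcs))
    rng = np.random.default_rng(seed)
    rows = rdcs.usable()
    errors = np.array([d.error for d in rows])
    d_obs = np.array([d.d_obs for d in rows])
    system = build_system(rdcs)
    accepted: list[SaupeTensor] = []
    for _ in range(n_trials):
        # unit draws scaled by the error bars: rescaling the bars rescales
        # the same draws, which keeps acceptance monotone in the bar width
        noise = rng.uniform(-1.0, 1.0, size=len(rows)) * errors
        b = (d_obs + noise) / system.scale
        from dataclasses import replace as _replace

        trial = solve(_replace(system, b=b))
        if satisfies_within_error(trial.tensor, rdcs):
            accepted.append(trial.tensor)
    return SolutionEnsemble(
        best=best, accepted=accepted, n_trials=n_trials,
        n_within_error=len(accepted), seed=seed,
    )


@dataclass
class ErrorReport:
    residuals: dict[int, float]  # |d_obs - d_calc| (Hz) by 1-based index
    violations: list[int]  # indices with residual > error (+slack)
    omitted: list[int]  # indices excluded from the final fit
    rmsd: float  # Hz, over included equations
    q_factor: float
    correlation: list[tuple[float, float]]  # (d_obs, d_calc), equation order


def q_factor(pairs) -> float:
    """Q = rms(d_calc - d_obs) / rms(d_obs) over (d_obs, d_calc) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("q_factor of an empty set is undefined")
    obs = np.array([p[0] for p in pairs])
    calc = np.array([p[1] for p in pairs])
    denom = float(np.sqrt(np.mean(obs**2)))
    if denom == 0.0:
        raise ZeroDivisionError("Q-factor undefined: all observed couplings are zero")
    return float(np.sqrt(np.mean((calc - obs) ** 2)) / denom)


def error_analysis(
    rdcs: RDCSet, tensor: SaupeTensor, omitted: list[int] | None = None
) -> ErrorReport:
    """Per-equation residuals, violation flags, RMSD and Q for one tensor."""
    rows = rdcs.usable()
    if not rows:
        raise EmptySystemError("no selected, observed equations to analyse")
    residuals: dict[int, float] = {}
    violations: list[int] = []
    correlation: list[tuple[float, float]] = []
    omitted = list(omitted or [])
    included_sq: list[float] = []
    included_pairs: list[tuple[float, float]] = []
    for d in rows:
        calc = back_calculate(tensor, d)
        resid = abs(d.d_obs - calc)
        residuals[d.index] = resid
        correlation.append((d.d_obs, calc))
        if d.index in omitted:
            continue
        if resid > d.error + VIOLATION_ATOL:
            violations.append(d.index)
        included_sq.append(resid**2)
        included_pairs.append((d.d_obs, calc))
    rmsd = float(np.sqrt(np.mean(included_sq))) if included_sq else 0.0
    q = q_factor(included_pairs) if included_pairs else float("nan")
    return ErrorReport(
        residuals=residuals, violations=violations, omitted=omitted,
        rmsd=rmsd, q_factor=q, correlation=correlation,
    )


def iterative_rejection(
    rdcs: RDCSet, max_iter: int = 100
) -> tuple[SvdSolution, list[int]]:
    """Greedy rejection of violating equations, one worst violator at a time.

    Repeats fit -> flag violations -> drop the largest violator -> refit,
    stopping when no violations remain, fewer than 5 equations would be
    left, or ``max_iter`` removals have been made.  Returns the final fit
    and the omitted indices in removal order.
    """
    omitted: list[int] = []
    current = rdcs
    solution = solve(build_system(current))
    for _ in range(max_iter):
        report = error_analysis(current, solution.tensor)
        if not report.violations:
            break
        if len(current.usable()) - 1 < 5:
            import warnings

            warnings.warn(
                "stopping rejection: fewer than 5 equations would remain",
                UserWarning, stacklevel=2,
            )
            break
        worst = max(report.violations, key=lambda i: report.residuals[i])
        omitted.append(worst)
        mask = current.selection.copy()
        mask[worst - 1] = False
        current = current.with_selection(mask)
        solution = solve(build_system(current))
    return solution, omitted


@dataclass
class ValidationResult:
    """Outcome of cross-media localized validation."""

    flagged: set  # 1-based indices violating in every medium
    per_medium: dict  # label -> (SvdSolution after rejection, omitted, violation set)


def localized_validation(media: dict, max_iter: int = 400) -> ValidationResult:
    """Identify locally distorted rows by combining evidence across media.

    Per alignment medium: run greedy iterative rejection, refit, and flag
    every equation whose residual against the refined tensor exceeds its
    error.  A row is reported as structurally suspect only when it is
    flagged in *every* medium — independent identification by several media
    is what makes a local violation trustworthy, since a single-medium flag
    can be a noise outlier or a residual tensor-estimate error.
    """
    per_medium = {}
    vsets = []
    for label, rdcs in media.items():
        solution, omitted = iterative_rejection(rdcs, max_iter=max_iter)
        vset = {
            d.index
            for d in rdcs.usable()
            if abs(back_calculate(solution.tensor, d) - d.d_obs)
            > d.error + VIOLATION_ATOL
        }
        per_medium[label] = (solution, omitted, vset)
        vsets.append(vset)
    flagged = set.intersection(*vsets) if vsets else set()
    return ValidationResult(flagged=flagged, per_medium=per_medium)


@dataclass
class MediumReport:
    medium_label: str
    tensor_s5: tuple[float, float, float, float, float]
    n_trials: int
    n_within_error: int
    principal: tuple[float, float, float]
    euler: tuple[float, float, float]
    da_by_pair: dict[str, float]
    rhombicity: float
    rmsd: float
    q_factor: float
    residuals: dict[int, float]
    violations: list[int]
    omitted: list[int]
    correlation: list[tuple[float, float]]
    sf_points_2d: list[SFPoint]
    sf_points_3d: list[SFPoint]
    error: str | None = None  # set when the medium could not be analysed


@dataclass
class FullReport:
    media: list[MediumReport]
    metadata: dict

    def to_dict(self) -> dict:
        out = {"metadata": dict(self.metadata), "media": []}
        for m in self.media:
            if m.error is not None:
                out["media"].append({"medium_label": m.medium_label, "error": m.error})
                continue
            out["media"].append({
                "medium_label": m.medium_label,
                "tensor_s5": list(m.tensor_s5),
                "n_trials": m.n_trials,
                "n_within_error": m.n_within_error,
                "principal": list(m.principal),
                "euler": list(m.euler),
                "da_by_pair": dict(m.da_by_pair),
                "rhombicity": m.rhombicity,
                "rmsd": m.rmsd,
                "q_factor": m.q_factor,
                "residuals": {str(k): v for k, v in m.residuals.items()},
                "violations": list(m.violations),
                "omitted": list(m.omitted),
                "correlation": [list(p) for p in m.correlation],
                "sf_points_2d": [list(vars(p).values()) for p in m.sf_points_2d],
                "sf_points_3d": [list(vars(p).values()) for p in m.sf_points_3d],
            })
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "FullReport":
        media = []
        for m in d["media"]:
            if "error" in m and "tensor_s5" not in m:
                media.append(MediumReport(
                    medium_label=m["medium_label"], tensor_s5=(0.0,) * 5,
                    n_trials=0, n_within_error=0, principal=(0.0,) * 3,
                    euler=(0.0,) * 3, da_by_pair={}, rhombicity=float("nan"),
                    rmsd=float("nan"), q_factor=float("nan"), residuals={},
                    violations=[], omitted=[], correlation=[],
                    sf_points_2d=[], sf_points_3d=[], error=m["error"],
                ))
                continue
            media.append(MediumReport(
                medium_label=m["medium_label"],
                tensor_s5=tuple(m["tensor_s5"]),
                n_trials=m["n_trials"],
                n_within_error=m["n_within_error"],
                principal=tuple(m["principal"]),
                euler=tuple(m["euler"]),
                da_by_pair=dict(m["da_by_pair"]),
                rhombicity=m["rhombicity"],
                rmsd=m["rmsd"],
                q_factor=m["q_factor"],
                residuals={int(k): v for k, v in m["residuals"].items()},
                violations=list(m["violations"]),
                omitted=list(m["omitted"]),
                correlation=[tuple(p) for p in m["correlation"]],
                sf_points_2d=[SFPoint(*p) for p in m["sf_points_2d"]],
                sf_points_3d=[SFPoint(*p) for p in m["sf_points_3d"]],
            ))
        return cls(media=media, metadata=dict(d["metadata"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FullReport":
        return cls.from_dict(json.loads(text))


def _medium_report(
    rdcs: RDCSet, error_threshold: float | None, n_trials: int, seed: int
) -> MediumReport:
    work = _with_errors(rdcs, error_threshold)
    ensemble = monte_carlo_solutions(work, n_trials=n_trials, seed=seed)
    decomp = diagonalize(ensemble.best.tensor)
    da, rhomb = anisotropy(decomp, REPORT_PAIRS)
    report = error_analysis(work, ensemble.best.tensor)
    return MediumReport(
        medium_label=rdcs.medium_label,
        tensor_s5=ensemble.best.tensor.s5,
        n_trials=n_trials,
        n_within_error=ensemble.n_within_error,
        principal=decomp.principal,
        euler=decomp.euler,
        da_by_pair=da,
        rhombicity=rhomb,
        rmsd=report.rmsd,
        q_factor=report.q_factor,
        residuals=report.residuals,
        violations=report.violations,
        omitted=report.omitted,
        correlation=report.correlation,
        sf_points_2d=sf_plot_data(ensemble, "2d"),
        sf_points_3d=sf_plot_data(ensemble, "3d"),
    )


def full_report(
    media,
    error_threshold: float | None = None,
    n_trials: int = 200,
    seed: int = 0,
    metadata: dict | None = None,
) -> FullReport:
    """Aggregate solve / Monte Carlo / decomposition / error analysis / SF
    datasets for every alignment medium into one record.

    ``error_threshold`` (Hz), when given, replaces the per-row error bars for
    both the Monte Carlo sampling and the violation checks.  A medium whose
    system cannot be solved contributes a block carrying an error marker
    instead of aborting the whole report.
    """
    media = list(media)
    if not media:
        raise ValueError("full_report needs at least one alignment medium")
    blocks = []
    for k, rdcs in enumerate(media):
        try:
            blocks.append(_medium_report(rdcs, error_threshold, n_trials, seed + k))
        except (EmptySystemError, np.linalg.LinAlgError, ZeroDivisionError) as exc:
            blocks.append(MediumReport(
                medium_label=rdcs.medium_label, tensor_s5=(0.0,) * 5,
                n_trials=n_trials, n_within_error=0, principal=(0.0,) * 3,
                euler=(0.0,) * 3, da_by_pair={}, rhombicity=float("nan"),
                rmsd=float("nan"), q_factor=float("nan"), residuals={},
                violations=[], omitted=[], correlation=[],
                sf_points_2d=[], sf_points_3d=[], error=str(exc),
            ))
    meta = {
        "error_threshold": error_threshold,
        "n_trials": n_trials,
        "seed": seed,
        "timestamp": metadata.get("timestamp") if metadata else time.strftime(
            "%Y-%m-%dT%H:%M:%S"
        ),
    }
    if metadata:
        meta.update(metadata)
    return FullReport(media=blocks, metadata=meta)


@dataclass
class EnsembleResult:
    reports: list  # FullReport per readable input, error dict per unreadable
    ranking_by_rmsd: list[int]  # input positions, best (lowest) first
    ranking_by_q: list[int]


def ensemble_analysis(paths, error_threshold: float | None = None,
                      n_trials: int = 200, seed: int = 0) -> EnsembleResult:
    """Run a full report for every data file and rank the files by fitness.

    Rankings are 0-based positions into ``paths`` ordered by mean RMSD and by
    mean Q-factor over each file's media; unreadable files are reported as
    error entries and excluded from the rankings.
    """
    from .io import read_redcat_file

    reports = []
    scores = []
    for pos, path in enumerate(paths):
        try:
            rdcs = read_redcat_file(path)
            rep = full_report([rdcs], error_threshold=error_threshold,
                              n_trials=n_trials, seed=seed,
                              metadata={"path": str(path)})
            reports.append(rep)
            ok = [m for m in rep.media if m.error is None]
            if ok:
                scores.append((pos,
                               float(np.mean([m.rmsd for m in ok])),
                               float(np.mean([m.q_factor for m in ok]))))
        except OSError as exc:
            reports.append({"path": str(path), "error": str(exc)})
    by_rmsd = [p for p, r, _ in sorted(scores, key=lambda t: t[1])]
    by_q = [p for p, _, q in sorted(scores, key=lambda t: t[2])]
    return EnsembleResult(reports=reports, ranking_by_rmsd=by_rmsd,
                          ranking_by_q=by_q)
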