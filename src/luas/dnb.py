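"""Sliding-window dynamic-network-biomarker (DNB) analysis.

A DNB module is a gene group whose within-module standard deviation and
correlation rise sharply — while its correlation with the rest of the
transcriptome stays low — just before a critical transition. For each sample
window along a ranked cohort, candidate modules are found by average-linkage
hierarchical clustering of high-variance genes on the distance 1 - |r|, and
each module is scored with the composite index

    CI = SD_in * PCC_in / PCC_out

where SD_in is the mean within-module sample SD, PCC_in the mean absolute
within-module Pearson correlation, and PCC_out the mean absolute correlation
between module genes and all other genes. The tipping point is the window
whose best module maximizes CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic import ExpressionMatrix

__all__ = [
    "DNBModule",
    "DNBParams",
    "CompositeIndexTrace",
    "window_modules",
    "composite_index",
    "sliding_dnb",
]

EPS_PCC_OUT = 1e-6


@dataclass(frozen=True)
class DNBModule:
    genes: tuple[str, ...]
    window: int

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a DNB module needs at least 2 genes")


@dataclass(frozen=True)
class DNBParams:
    window_size: int = 10
    step: int = 1
    variance_quantile: float = 0.75
    cut_height: float = 0.4
    min_module_size: int = 3


@dataclass
class CompositeIndexTrace:
    """Per-window composite index components and the tipping window."""

    table: pd.DataFrame  # window, start, SD_in, PCC_in, PCC_out, CI, module_size
    modules: list[DNBModule | None]
    window_samples: list[list[str]]
    params: DNBParams
    eps_triggered: bool = False

    @property
    def tipping_window(self) -> int | None:
        """Argmax-CI window index; ties go to the earlier window. None when
        no window produced any module."""
        ci = self.table["CI"].to_numpy()
        if not (ci > 0).any() and all(m is None for m in self.modules):
            return None
        return int(np.argmax(ci))

    @property
    def tipping_module(self) -> DNBModule | None:
        k = self.tipping_window
        return None if k is None else self.modules[k]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _abs_corr(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """|Pearson r| matrix between rows of x (and rows of y); zero-variance
    rows contribute r = 0."""
    def _std(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = rows.mean(axis=1, keepdims=True)
        c = rows - mu
        norm = np.sqrt((c**2).sum(axis=1))
        ok = norm > 0
        c[ok] = c[ok] / norm[ok, None]
        c[~ok] = 0.0
        return c, ok

    cx, _ = _std(np.asarray(x, dtype=float).copy())
    cy, _ = _std(np.asarray(y, dtype=float).copy()) if y is not None else (cx, None)
    r = np.clip(np.abs(cx @ cy.T), 0.0, 1.0)
    return r


def _windows(n: int, size: int, step: int) -> list[int]:
    if size > n:
        raise ValueError(f"window size {size} exceeds cohort size {n}")
    return list(range(0, n - size + 1, step))


def window_modules(
    expr: ExpressionMatrix,
    ranking: list[str],
    params: DNBParams = DNBParams(),
) -> list[list[DNBModule]]:
    """Candidate DNB modules per sliding window.

    Within each window, genes with SD at or above the ``variance_quantile``
    of window SDs are clustered by average linkage on 1 - |r|; clusters cut
    at ``cut_height``; clusters smaller than ``min_module_size`` dropped.
    """
    vals = expr.values[ranking].to_numpy()
    genes = expr.genes.to_numpy(dtype=object)
    out: list[list[DNBModule]] = []
    for wi, start in enumerate(_windows(len(ranking), params.window_size, params.step)):
        win = vals[:, start : start + params.window_size]
        sds = win.std(axis=1, ddof=1)
        positive = sds > 0
        if not positive.any():
            out.append([])
            continue
        thresh = np.quantile(sds[positive], params.variance_quantile)
        keep = positive & (sds >= thresh)
        idx = np.flatnonzero(keep)
        mods: list[DNBModule] = []
        if idx.size >= 2:
            dist = 1.0 - _abs_corr(win[idx])
            np.fill_diagonal(dist, 0.0)
            dist = (dist + dist.T) / 2.0
            Z = linkage(squareform(dist, checks=False), method="average")
            labels = fcluster(Z, t=params.cut_height, criterion="distance")
            for lab in np.unique(labels):
                members = idx[labels == lab]
                if members.size >= params.min_module_size:
                    mods.append(
                        DNBModule(genes=tuple(sorted(genes[members])), window=wi)
                    )
        out.append(mods)
    return out


def composite_index(
    expr_window: pd.DataFrame, module: tuple[str, ...] | DNBModule
) -> tuple[float, float, float, float]:
    """(SD_in, PCC_in, PCC_out, CI) of a module within one sample window.

    ``expr_window`` is genes x window-samples over *all* genes; genes with
    zero window variance contribute r = 0 to the correlation averages.
    """
    mod_genes = list(module.genes) if isinstance(module, DNBModule) else list(module)
    if len(mod_genes) < 2:
        raise ValueError("module must contain at least 2 genes (PCC_in undefined)")
    missing = set(mod_genes) - set(expr_window.index)
    if missing:
        raise ValueError(f"module genes not in the window matrix: {sorted(missing)}")
    if expr_window.shape[1] < 3:
        raise ValueError("window needs at least 3 samples")
    inside = expr_window.loc[mod_genes].to_numpy()
    out_idx = expr_window.index.difference(mod_genes)
    sd_in = float(inside.std(axis=1, ddof=1).mean())
    r_in = _abs_corr(inside)
    m = len(mod_genes)
    pcc_in = float(r_in[np.triu_indices(m, k=1)].mean())
    if len(out_idx) == 0:
        pcc_out = pcc_in  # no outside genes: ratio cancels to SD_in * 1
    else:
        outside = expr_window.loc[out_idx].to_numpy()
        pcc_out = float(_abs_corr(inside, outside).mean())
    ci = sd_in * pcc_in / max(pcc_out, EPS_PCC_OUT)
    return sd_in, pcc_in, pcc_out, ci


def sliding_dnb(
    expr: ExpressionMatrix,
    ranking: list[str],
    params: DNBParams = DNBParams(),
) -> CompositeIndexTrace:
    """Full sliding-window DNB scan along a ranking.

    For each window the candidate module with the largest CI is recorded;
    the tipping point is the argmax-CI window (ties to the earlier window).
    Windows without candidate modules get CI = 0.
    """
    starts = _windows(len(ranking), params.window_size, params.step)
    per_window = window_modules(expr, ranking, params)
    rows = []
    best_modules: list[DNBModule | None] = []
    samples_per_window: list[list[str]] = []
    eps_triggered = False
    for wi, start in enumerate(starts):
        win_samples = ranking[start : start + params.window_size]
        win = expr.values[win_samples]
        best: tuple[float, float, float, float] | None = None
        best_mod: DNBModule | None = None
        for mod in per_window[wi]:
            comp = composite_index(win, mod)
            if best is None or comp[3] > best[3]:
                best, best_mod = comp, mod
        if best is None:
            best = (0.0, 0.0, 0.0, 0.0)
        if best_mod is not None and best[2] < EPS_PCC_OUT:
            eps_triggered = True
        rows.append(
            {
                "window": wi,
                "start": start,
                "SD_in": best[0],
                "PCC_in": best[1],
                "PCC_out": best[2],
                "CI": best[3],
                "module_size": 0 if best_mod is None else len(best_mod.genes),
            }
        )
        best_modules.append(best_mod)
        samples_per_window.append(win_samples)
    return CompositeIndexTrace(
        table=pd.DataFrame(rows),
        modules=best_modules,
        window_samples=samples_per_window,
        params=params,
        eps_triggered=eps_triggered,
    )
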