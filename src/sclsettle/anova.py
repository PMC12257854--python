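"""Repeated-measures ANOVA for the cohort thickness table.

Split-plot (mixed) design: up to two within-subject factors (time, region)
and one between-subject factor (group).  Within effects are computed from
orthonormal contrast scores of the per-subject cell vectors; each within
effect is tested against its own subject-by-effect error stratum, with the
Greenhouse-Geisser epsilon estimated from the pooled within-group
covariance of the contrast scores.  Post hoc pairwise comparisons use
Bonferroni-adjusted t tests.

Sums of squares use cell-size-weighted grand means; for the balanced
designs the generator produces this coincides with Type III.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnovaDesignError


def orthonormal_contrast(k):
    """(k-1) x k orthonormal contrast matrix (rows span mean-free space)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis[:, : k - 1])
    return q.T  # (k-1, k); rows orthonormal, each orthogonal to the mean


def gg_epsilon(cov, contrast):
    """Greenhouse-Geisser epsilon for an effect contrast.

    epsilon = tr(M)^2 / (q * tr(M^2)) with M = C S C'; bounded to
    [1/q, 1] (exactly 1 when q = 1, i.e. a 2-level factor).
    """
    M = contrast @ cov @ contrast.T
    q = M.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (q * tr2)
    return float(np.clip(eps, 1.0 / q, 1.0))


@dataclass
class RmAnovaResults:
    """ANOVA table plus the design info needed for post hoc tests."""

    anova_table: pd.DataFrame
    n_subjects: int
    n_dropped: int
    groups: dict
    _design: dict = field(default_factory=dict, repr=False)

    def summary(self):
        lines = [
            "Repeated-measures ANOVA (Greenhouse-Geisser corrected)",
            f"  subjects analyzed: {self.n_subjects}"
            + (f" (dropped {self.n_dropped} incomplete)" if self.n_dropped else ""),
        ]
        tbl = self.anova_table.copy()
        with pd.option_context("display.float_format", "{:0.4g}".format):
            lines.append(tbl.to_string(index=False))
        return "\n".join(lines)

    def pairwise(self, factor, alpha=0.05):
        """Bonferroni-adjusted pairwise comparisons for one factor."""
        d = self._design
        if factor == d.get("between"):
            groups = d["group_of"]
            scores = d["subject_means"]
            levels = sorted(set(groups))
            rows = []
            pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
            m = len(pairs)
            for a, b in pairs:
                xa = scores[np.asarray(groups) == a]
                xb = scores[np.asarray(groups) == b]
                t, p = stats.ttest_ind(xa, xb)
                rows.append(dict(A=a, B=b, mean_A=xa.mean(), mean_B=xb.mean(),
                                 t=float(t), p_unc=float(p),
                                 p_bonf=bonferroni(p, m)))
            return pd.DataFrame(rows)
        if factor not in d["within"]:
            raise AnovaDesignError(f"unknown factor {factor!r}")
        # collapse the subject cell matrix over the other within factor
        Y = d["Y"]
        levels = d["levels"][factor]
        axis_levels = {f: d["levels"][f] for f in d["within"]}
        shape = [len(axis_levels[f]) for f in d["within"]]
        Yr = Y.reshape(len(Y), *shape)
        ax = 1 + d["within"].index(factor)
        other_axes = tuple(i for i in range(1, Yr.ndim) if i != ax)
        M = Yr.mean(axis=other_axes) if other_axes else Yr
        rows = []
        pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
        npairs = len(pairs)
        for i, j in pairs:
            t, p = stats.ttest_rel(M[:, i], M[:, j])
            rows.append(dict(A=levels[i], B=levels[j],
                             mean_A=float(M[:, i].mean()), mean_B=float(M[:, j].mean()),
                             t=float(t), p_unc=float(p), p_bonf=bonferroni(p, npairs)))
        return pd.DataFrame(rows)


def bonferroni(p, m):
    """Bonferroni adjustment: min(1, m * p)."""
    return float(min(1.0, m * p))


class RepeatedMeasuresAnova:
    """Model object; ``fit()`` returns :class:`RmAnovaResults`.

    Parameters
    ----------
    data : DataFrame
        Long format with one row per (subject, within-cells) observation.
    dv, subject : str
        Column names of the dependent variable and the subject id.
    within : sequence of str
        One or two within-subject factor columns.
    between : str or None
        Optional between-subject factor column.
    """

    def __init__(self, data, dv, subject, within, between=None):
        self.data = data
        self.dv = dv
        self.subject = subject
        self.within = [within] if isinstance(within, str) else list(within)
        if not 1 <= len(self.within) <= 2:
            raise AnovaDesignError("within must name one or two factors")
        self.between = between

    def fit(self):
        df = self.data.copy()
        levels = {f: sorted(df[f].unique()) for f in self.within}
        cells = [len(levels[f]) for f in self.within]
        p = int(np.prod(cells))
        wide = df.pivot_table(
            index=self.subject, columns=self.within, values=self.dv, aggfunc="mean"
        )
        # enforce factor-major ordering of the columns
        if len(self.within) == 1:
            wide = wide.reindex(columns=levels[self.within[0]])
        else:
            cols = pd.MultiIndex.from_product([levels[f] for f in self.within])
            wide = wide.reindex(columns=cols)
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        subjects = complete.index.to_numpy()
        Y = complete.to_numpy(float)
        n = len(complete)
        if self.between is not None:
            gmap = df.drop_duplicates(self.subject).set_index(self.subject)[self.between]
            group_of = gmap.loc[subjects].to_numpy()
        else:
            group_of = np.array(["_all"] * n)
        glevels = sorted(set(group_of))
        k = len(glevels)
        counts = {g: int(np.sum(group_of == g)) for g in glevels}
        if n < 2 or any(c < 2 for c in counts.values()):
            raise AnovaDesignError(
                f"need >= 2 complete subjects per group, got {counts}"
            )

        # pooled within-group covariance of the cell vectors
        S = np.zeros((p, p))
        for g in glevels:
            yg = Y[group_of == g]
            S += (yg - yg.mean(axis=0)).T @ (yg - yg.mean(axis=0))
        S /= max(n - k, 1)

        contrasts = {f: orthonormal_contrast(len(levels[f])) for f in self.within}
        effect_contrasts = {}
        if len(self.within) == 1:
            f0 = self.within[0]
            effect_contrasts[f0] = contrasts[f0]
        else:
            f0, f1 = self.within
            a, b = cells
            j0 = np.full((1, a), 1.0 / np.sqrt(a))
            j1 = np.full((1, b), 1.0 / np.sqrt(b))
            # scaling by sqrt(levels averaged over) keeps classical SS units
            effect_contrasts[f0] = np.kron(contrasts[f0], j1 * np.sqrt(b))
            effect_contrasts[f1] = np.kron(j0 * np.sqrt(a), contrasts[f1])
            effect_contrasts[f"{f0}:{f1}"] = np.kron(contrasts[f0], contrasts[f1])

        rows = []
        # between-subject effect
        subject_means = Y.mean(axis=1)
        grand = subject_means.mean()
        if self.between is not None:
            ss_g = p * sum(
                counts[g] * (subject_means[group_of == g].mean() - grand) ** 2
                for g in glevels
            )
            ss_sg = p * sum(
                np.sum((subject_means[group_of == g]
                        - subject_means[group_of == g].mean()) ** 2)
                for g in glevels
            )
            df1, df2 = k - 1, n - k
            F = (ss_g / df1) / (ss_sg / df2) if ss_sg > 0 else np.inf
            rows.append(dict(effect=self.between, F=F, df1=df1, df2=df2,
                             eps=np.nan, p=float(stats.f.sf(F, df1, df2)),
                             p_gg=float(stats.f.sf(F, df1, df2))))

        for name, C in effect_contrasts.items():
            q = C.shape[0]
            U = Y @ C.T  # (n, q) subject scores
            ubar = U.mean(axis=0)
            ss_eff = n * float(ubar @ ubar)
            ss_int = 0.0
            resid = np.empty_like(U)
            for g in glevels:
                m = group_of == g
                ug = U[m].mean(axis=0)
                ss_int += counts[g] * float((ug - ubar) @ (ug - ubar))
                resid[m] = U[m] - ug
            ss_err = float(np.sum(resid**2))
            df_err = q * (n - k)
            eps = gg_epsilon(S, C)
            F = (ss_eff / q) / (ss_err / df_err) if ss_err > 0 else np.inf
            p_unc = float(stats.f.sf(F, q, df_err))
            p_gg = float(stats.f.sf(F, q * eps, df_err * eps))
            rows.append(dict(effect=name, F=F, df1=q, df2=df_err,
                             eps=eps, p=p_unc, p_gg=p_gg))
            if self.between is not None:
                Fi = (ss_int / (q * (k - 1))) / (ss_err / df_err) if ss_err > 0 else np.inf
                p_unc_i = float(stats.f.sf(Fi, q * (k - 1), df_err))
                p_gg_i = float(stats.f.sf(Fi, q * (k - 1) * eps, df_err * eps))
                rows.append(dict(effect=f"{name}:{self.between}", F=Fi,
                                 df1=q * (k - 1), df2=df_err, eps=eps,
                                 p=p_unc_i, p_gg=p_gg_i))

        table = pd.DataFrame(rows)
        design = dict(
            Y=Y, within=self.within, levels=levels, between=self.between,
            group_of=group_of, subject_means=subject_means,
        )
        return RmAnovaResults(table, n, n_dropped, counts, design)


def rm_anova(data, dv="mean_um", subject="eye", within=("time_min", "region"),
             between="group"):
    """Convenience wrapper around :class:`RepeatedMeasuresAnova`."""
    return RepeatedMeasuresAnova(data, dv, subject, within, between).fit()
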