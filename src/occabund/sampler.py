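"""Component-wise adaptive MCMC for the integrated joint posterior.

Sampling scheme:

* scalar parameters (intercepts, slopes, SDs, the home-range diameter) move
  by adaptive random-walk Metropolis;
* random-effect vectors move by *element-wise* vectorised Metropolis -- the
  full conditional of a vector factorises across its levels because every
  data row depends on exactly one element, so all elements are proposed at
  once and accepted or rejected independently via per-group log-likelihood
  deltas;
* the latent undetected-occupied counts ``u`` are updated by enumerated
  Gibbs over 0..(s - s_star);
* each (sigma, effects) hierarchy gets a joint scale move
  (sigma, eta) -> (c sigma, c eta) and each (mu, effects) pair a translation
  move (mu + delta, eta - delta), which break the funnel- and location-
  correlations that defeat single-site samplers in hierarchical models.

Proposal scales adapt by Robbins-Monro toward 44% acceptance during the
burn-in phase and are frozen afterwards.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy

_LOG2PI = math.log(2.0 * math.pi)
_CLIP = 1e-12
_SIGMA_FLOOR = 1e-4
_TARGET_ACC = 0.44


def _norm_sum_logpdf(v: np.ndarray, sd: float) -> float:
    if sd <= 0:
        return -np.inf
    return float(-0.5 * np.sum((v / sd) ** 2) - v.size * (math.log(sd) + 0.5 * _LOG2PI))


class Sampler:
    """One-chain sampler bound to a model's fit data (see ``occabund.model``)."""

    def __init__(self, model):
        self.model = model
        self.data = model._data
        self.short = model.timescale == "short"

    # -- probability / likelihood pieces ----------------------------------

    def _side_probs(self, st, side):
        d = self.data
        lp = st[f"mu_{side}"] + st[f"beta_{side}"] * d.Xf
        lp = lp + st[f"eta_g_{side}"][d.g] + st[f"eta_y_{side}"][d.y]
        if self.short:
            lp = lp + st[f"eta_m_{side}"][d.m]
        lp = lp + st[f"eps_{side}"]
        return np.clip(expit(lp), _CLIP, 1.0 - _CLIP)

    def _p_cap(self, st):
        d = self.data
        lp = st["mu_p"] + st["eta_g_p"][d.gcap] + st["eta_y_p"][d.ycap]
        if self.short:
            lp = lp + st["eta_m_p"][d.mcap]
        lp = lp + st["eps_p"]
        return np.clip(expit(lp), _CLIP, 1.0 - _CLIP)

    def _occ_ll(self, psi, rho):
        d = self.data
        miss_all = (1.0 - rho) ** d.k
        p_any = psi * (1.0 - miss_all)
        return (
            xlogy(d.sstar, psi)
            + xlogy(d.dd, rho)
            + xlog1py(d.sstar * d.k - d.dd, -rho)
            + xlog1py(d.s - d.sstar, -p_any)
        )

    def _pair_extra(self, st, psi, rho):
        """Per capture-row: latent-u binomial pmf + hyper-model normal."""
        d = self.data
        if d.n_cap == 0:
            return np.zeros(0)
        rho_p = rho[d.occ_idx]
        psi_p = psi[d.occ_idx]
        miss = (1.0 - rho_p) ** d.k_p
        psiC = psi_p * miss / (1.0 - psi_p * (1.0 - miss))
        u = st["u"]
        upmf = (
            gammaln(d.smax + 1)
            - gammaln(u + 1)
            - gammaln(d.smax - u + 1)
            + xlogy(u, psiC)
            + xlog1py(d.smax - u, -psiC)
        )
        Psi = (d.sstar_p + u) / d.s_p
        mean = (st["beta0"] + st["beta1"] * self.model._tr(Psi)
                + st["beta2"] * self.model._tr(rho_p))
        se = max(st["sigma_eps"], _SIGMA_FLOOR)
        hyp = -0.5 * ((st["logD"] - mean) / se) ** 2 - math.log(se) - 0.5 * _LOG2PI
        return upmf + hyp

    def _cap_ll(self, st):
        d = self.data
        if d.n_cap == 0:
            return np.zeros(0)
        p = self._p_cap(st)
        ps = 1.0 - (1.0 - p) ** d.t
        hug = (xlogy(d.n, p) + xlog1py(d.M * d.t - d.n, -p) - xlogy(d.M, ps))
        A = self.model._area(st["d_hr"])
        rate = np.exp(st["logD"]) * A * ps
        pois = xlogy(d.M, rate) - rate - gammaln(d.M + 1)
        return hug + pois

    # -- row-total targets -------------------------------------------------

    def _rt_occ_side(self, st):
        psi = self._side_probs(st, "psi")
        rho = self._side_probs(st, "rho")
        tot = self._occ_ll(psi, rho)
        if self.data.n_cap:
            tot = tot.copy()
            tot[self.data.occ_idx] += self._pair_extra(st, psi, rho)
        return tot

    def _rt_cap(self, st):
        return self._cap_ll(st)

    def _rt_pair(self, st):
        psi = self._side_probs(st, "psi")
        rho = self._side_probs(st, "rho")
        return self._pair_extra(st, psi, rho)

    def _rt_logD(self, st):
        return self._cap_ll(st) + self._rt_pair(st)

    # -- moves -------------------------------------------------------------

    def _scalar_move(self, st, name, prior, target, steps, rng, adapting, it):
        cur = st[name]
        prop = cur + math.exp(steps[name]) * rng.standard_normal()
        lp1 = prior.logpdf(prop)
        acc = False
        if np.isfinite(lp1) and not (name.startswith("sigma") and prop < _SIGMA_FLOOR):
            lp0 = prior.logpdf(cur)
            t0 = float(np.sum(target(st))) if target is not None else 0.0
            st[name] = prop
            t1 = float(np.sum(target(st))) if target is not None else 0.0
            if math.log(rng.random()) < (t1 + lp1) - (t0 + lp0):
                acc = True
            else:
                st[name] = cur
        if adapting:
            steps[name] += ((1.0 if acc else 0.0) - _TARGET_ACC) * (it + 1) ** -0.6

    def _vector_move(self, st, name, group, n_rows, target, prior_sd_name,
                     steps, rng, adapting, it):
        cur = st[name]
        if cur.size == 0:
            return
        prop = cur + np.exp(steps[name]) * rng.standard_normal(cur.size)
        ll0 = target(st)
        st[name] = prop
        ll1 = target(st)
        st[name] = cur
        delta_rows = ll1 - ll0
        delta = np.bincount(group, weights=delta_rows, minlength=cur.size)
        if prior_sd_name is not None:
            sd = max(st[prior_sd_name], _SIGMA_FLOOR)
            delta = delta + (cur**2 - prop**2) / (2.0 * sd * sd)
        acc = np.log(rng.random(cur.size)) < delta
        new = np.where(acc, prop, cur)
        st[name] = new
        if adapting:
            steps[name] += (acc.astype(float) - _TARGET_ACC) * (it + 1) ** -0.6

    def _scale_move(self, st, sigma_name, vec_name, target, steps, rng,
                    adapting, it, prior):
        key = f"scale:{sigma_name}"
        cur_sig = st[sigma_name]
        c = math.exp(math.exp(steps[key]) * rng.standard_normal())
        new_sig = c * cur_sig
        acc = False
        lp1 = prior.logpdf(new_sig)
        if np.isfinite(lp1) and new_sig >= _SIGMA_FLOOR:
            lp0 = prior.logpdf(cur_sig)
            cur_vec = st[vec_name]
            t0 = float(np.sum(target(st))) if target is not None else 0.0
            st[sigma_name] = new_sig
            st[vec_name] = c * cur_vec
            t1 = float(np.sum(target(st))) if target is not None else 0.0
            logr = (t1 + lp1) - (t0 + lp0) + math.log(c)
            if math.log(rng.random()) < logr:
                acc = True
            else:
                st[sigma_name] = cur_sig
                st[vec_name] = cur_vec
        if adapting:
            steps[key] += ((1.0 if acc else 0.0) - _TARGET_ACC) * (it + 1) ** -0.6

    def _scale_move_logD(self, st, steps, rng, adapting, it, prior):
        """(sigma_eps, logD) scale move around the current hyper mean."""
        d = self.data
        if d.n_cap == 0:
            return
        key = "scale:sigma_eps"
        cur_sig = st["sigma_eps"]
        c = math.exp(math.exp(steps[key]) * rng.standard_normal())
        new_sig = c * cur_sig
        acc = False
        lp1 = prior.logpdf(new_sig)
        if np.isfinite(lp1) and new_sig >= _SIGMA_FLOOR:
            lp0 = prior.logpdf(cur_sig)
            psi = self._side_probs(st, "psi")
            rho = self._side_probs(st, "rho")
            rho_p = rho[d.occ_idx]
            Psi = (d.sstar_p + st["u"]) / d.s_p
            mean = (st["beta0"] + st["beta1"] * self.model._tr(Psi)
                    + st["beta2"] * self.model._tr(rho_p))
            cur_logD = st["logD"]
            t0 = float(np.sum(self._cap_ll(st)))
            st["sigma_eps"] = new_sig
            st["logD"] = mean + c * (cur_logD - mean)
            t1 = float(np.sum(self._cap_ll(st)))
            logr = (t1 + lp1) - (t0 + lp0) + math.log(c)
            if math.log(rng.random()) < logr:
                acc = True
            else:
                st["sigma_eps"] = cur_sig
                st["logD"] = cur_logD
        if adapting:
            steps[key] += ((1.0 if acc else 0.0) - _TARGET_ACC) * (it + 1) ** -0.6

    def _translate_move(self, st, mu_name, vec_name, mu_prior, sd_name,
                        target, steps, rng, adapting, it):
        """mu + delta, effects - delta; likelihood-invariant unless a target
        is supplied (beta0/logD, where the Poisson term reacts)."""
        if st[vec_name].size == 0:
            return
        key = f"shift:{mu_name}:{vec_name}"
        delta = math.exp(steps[key]) * rng.standard_normal()
        cur_mu, cur_vec = st[mu_name], st[vec_name]
        lp0 = mu_prior.logpdf(cur_mu)
        lp1 = mu_prior.logpdf(cur_mu + delta)
        if sd_name is not None:
            sd = max(st[sd_name], _SIGMA_FLOOR)
            prop_vec = cur_vec - delta
            lp1 += _norm_sum_logpdf(prop_vec, sd)
            lp0 += _norm_sum_logpdf(cur_vec, sd)
        else:
            prop_vec = cur_vec + delta  # logD rides along with beta0
        t0 = float(np.sum(target(st))) if target is not None else 0.0
        if target is not None:
            st[mu_name] = cur_mu + delta
            st[vec_name] = prop_vec
            t1 = float(np.sum(target(st)))
        else:
            t1 = 0.0
        acc = math.log(rng.random()) < (t1 + lp1) - (t0 + lp0)
        if acc:
            st[mu_name] = cur_mu + delta
            st[vec_name] = prop_vec
        else:
            st[mu_name] = cur_mu
            st[vec_name] = cur_vec
        if adapting:
            steps[key] += ((1.0 if acc else 0.0) - _TARGET_ACC) * (it + 1) ** -0.6

    def _beta_shift_move(self, st, side, steps, rng, adapting, it):
        """beta_side + delta compensated by -delta on the plot effects of
        non-randomly selected plots; likelihood-invariant."""
        d = self.data
        mask = d.X_plot == 1
        if not mask.any():
            return
        key = f"shift:beta_{side}"
        beta_name = f"beta_{side}"
        vec_name = f"eta_g_{side}"
        delta = math.exp(steps[key]) * rng.standard_normal()
        prior = self.model.priors.for_scalar(beta_name)
        sd = max(st[f"sigma_g_{side}"], _SIGMA_FLOOR)
        cur_b, cur_v = st[beta_name], st[vec_name]
        sub = cur_v[mask]
        logr = (prior.logpdf(cur_b + delta) - prior.logpdf(cur_b)
                + _norm_sum_logpdf(sub - delta, sd) - _norm_sum_logpdf(sub, sd))
        acc = math.log(rng.random()) < logr
        if acc:
            st[beta_name] = cur_b + delta
            new_v = cur_v.copy()
            new_v[mask] -= delta
            st[vec_name] = new_v
        if adapting:
            steps[key] += ((1.0 if acc else 0.0) - _TARGET_ACC) * (it + 1) ** -0.6

    def _hyper_block_move(self, st, block, rng, adapting, it):
        """Joint Haario-style move for the collinear (beta0, beta1, beta2).

        The empirical covariance of the triple is accumulated during burn-in
        and used as the proposal shape (scaled 2.38^2/3), with a global
        scale adapted toward ~23% acceptance; frozen after burn-in.
        """
        if self.data.n_cap == 0:
            return
        m = self.model
        cur = np.array([st["beta0"], st["beta1"], st["beta2"]])
        if adapting:
            block["hist"].append(cur.copy())
        n_hist = len(block["hist"])
        if adapting and n_hist >= 100 and n_hist % 100 == 0:
            h = np.asarray(block["hist"][n_hist // 2:])
            block["chol"] = np.linalg.cholesky(
                np.cov(h.T) * (2.38**2 / 3) + 1e-6 * np.eye(3))
        prop = cur + math.exp(block["lscale"]) * (
            block["chol"] @ rng.standard_normal(3))
        priors = [m.priors.beta0, m.priors.beta1, m.priors.beta2]
        lp0 = sum(pr.logpdf(v) for pr, v in zip(priors, cur))
        lp1 = sum(pr.logpdf(v) for pr, v in zip(priors, prop))
        t0 = float(np.sum(self._rt_pair(st)))
        st["beta0"], st["beta1"], st["beta2"] = prop
        t1 = float(np.sum(self._rt_pair(st)))
        acc = math.log(rng.random()) < (t1 + lp1) - (t0 + lp0)
        if not acc:
            st["beta0"], st["beta1"], st["beta2"] = cur
        if adapting:
            block["lscale"] += ((1.0 if acc else 0.0) - 0.234) * (it + 1) ** -0.6

    def _gibbs_u(self, st, rng):
        d = self.data
        if d.n_cap == 0 or d.smax.max() == 0:
            return
        psi = self._side_probs(st, "psi")
        rho = self._side_probs(st, "rho")
        rho_p = rho[d.occ_idx]
        psi_p = psi[d.occ_idx]
        miss = (1.0 - rho_p) ** d.k_p
        psiC = psi_p * miss / (1.0 - psi_p * (1.0 - miss))
        grid = np.arange(d.smax.max() + 1)
        smx = d.smax[:, None]
        valid = grid[None, :] <= smx
        rest = np.where(valid, smx - grid[None, :], 0)
        logw = (
            gammaln(smx + 1) - gammaln(grid[None, :] + 1) - gammaln(rest + 1)
            + xlogy(grid[None, :], psiC[:, None])
            + xlog1py(rest, -psiC[:, None])
        )
        Psi = (d.sstar_p[:, None] + grid[None, :]) / d.s_p[:, None]
        mean = (st["beta0"] + st["beta1"] * self.model._tr(Psi)
                + st["beta2"] * self.model._tr(rho_p)[:, None])
        se = max(st["sigma_eps"], _SIGMA_FLOOR)
        logw = logw - 0.5 * ((st["logD"][:, None] - mean) / se) ** 2
        logw = np.where(valid, logw, -np.inf)
        st["u"] = np.argmax(logw + rng.gumbel(size=logw.shape), axis=1).astype(float)

    # -- the chain ---------------------------------------------------------

    def _init_steps(self):
        m = self.model
        steps = {}
        for name in m._scalar_names:
            steps[name] = math.log(0.1)
        for name, _, size in m._vector_specs:
            steps[name] = np.full(size, math.log(0.5))
        for sig, _vec, _t in self._scale_pairs():
            steps[f"scale:{sig}"] = math.log(0.1)
        steps["scale:sigma_eps"] = math.log(0.1)
        for mu, vec in self._shift_pairs():
            steps[f"shift:{mu}:{vec}"] = math.log(0.1)
        steps["shift:beta0:logD"] = math.log(0.1)
        steps["shift:beta_rho"] = math.log(0.1)
        steps["shift:beta_psi"] = math.log(0.1)
        return steps

    def _scale_pairs(self):
        pairs = [
            ("sigma_g_rho", "eta_g_rho", self._rt_occ_side),
            ("sigma_y_rho", "eta_y_rho", self._rt_occ_side),
            ("sigma_rho", "eps_rho", self._rt_occ_side),
            ("sigma_g_psi", "eta_g_psi", self._rt_occ_side),
            ("sigma_y_psi", "eta_y_psi", self._rt_occ_side),
            ("sigma_psi", "eps_psi", self._rt_occ_side),
            ("sigma_g_p", "eta_g_p", self._rt_cap),
            ("sigma_y_p", "eta_y_p", self._rt_cap),
            ("sigma_p", "eps_p", self._rt_cap),
        ]
        if self.short:
            pairs += [
                ("sigma_m_rho", "eta_m_rho", self._rt_occ_side),
                ("sigma_m_psi", "eta_m_psi", self._rt_occ_side),
                ("sigma_m_p", "eta_m_p", self._rt_cap),
            ]
        return pairs

    def _shift_pairs(self):
        sides = [("mu_rho", "rho"), ("mu_psi", "psi"), ("mu_p", "p")]
        pairs = []
        for mu, suf in sides:
            vecs = [f"eta_g_{suf}", f"eta_y_{suf}", f"eps_{suf}"]
            if self.short:
                vecs.append(f"eta_m_{suf}")
            pairs += [(mu, v) for v in vecs]
        return pairs

    def run(self, st, n_iter, n_burn, thin, rng, record):
        """Run one chain in place; ``record(st, it)`` is called for retained
        iterations."""
        m = self.model
        steps = self._init_steps()
        scalar_targets = m._scalar_targets(self)
        sigma_of = {}
        for sig, vec, _t in self._scale_pairs():
            sigma_of[vec] = sig

        vec_specs = []
        d = self.data
        for name, _labels, _size in m._vector_specs:
            if name in ("logD", "u"):
                continue
            suf = name.split("_")[-1]
            n_rows = d.n_cap if suf == "p" else d.n_occ
            if name.startswith("eps_"):
                group = np.arange(n_rows)
            elif name.startswith("eta_g_"):
                group = d.gcap if suf == "p" else d.g
            elif name.startswith("eta_y_"):
                group = d.ycap if suf == "p" else d.y
            else:
                group = (d.mcap if d.mcap is not None else np.zeros(0, int)) \
                    if suf == "p" else d.m
            target = self._rt_cap if suf == "p" else self._rt_occ_side
            vec_specs.append((name, group, n_rows, target, sigma_of[name]))

        shift_pairs = self._shift_pairs()
        scale_pairs = self._scale_pairs()
        block = {"hist": [], "chol": np.linalg.cholesky(0.05 * np.eye(3)),
                 "lscale": 0.0}

        for it in range(n_iter):
            adapting = it < n_burn
            for name, (prior, target) in scalar_targets.items():
                self._scalar_move(st, name, prior, target, steps, rng,
                                  adapting, it)
            for name, group, n_rows, target, sdn in vec_specs:
                self._vector_move(st, name, group, n_rows, target, sdn,
                                  steps, rng, adapting, it)
            if d.n_cap:
                self._vector_move(st, "logD", np.arange(d.n_cap), d.n_cap,
                                  self._rt_logD, None, steps, rng, adapting, it)
                self._gibbs_u(st, rng)
                self._hyper_block_move(st, block, rng, adapting, it)
            for sig, vec, target in scale_pairs:
                self._scale_move(st, sig, vec, target, steps, rng, adapting,
                                 it, m.priors.sigma)
            self._scale_move_logD(st, steps, rng, adapting, it, m.priors.sigma)
            for mu, vec in shift_pairs:
                self._translate_move(st, mu, vec, m.priors.for_scalar(mu),
                                     sigma_of[vec], None, steps, rng,
                                     adapting, it)
            self._beta_shift_move(st, "rho", steps, rng, adapting, it)
            self._beta_shift_move(st, "psi", steps, rng, adapting, it)
            if d.n_cap:
                self._translate_move(st, "beta0", "logD", m.priors.beta0,
                                     None, self._rt_cap, steps, rng,
                                     adapting, it)
            if it >= n_burn and (it - n_burn) % thin == 0:
                record(st, it)
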