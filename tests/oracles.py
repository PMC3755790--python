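"""Independent brute-force oracles used to check the implementation.

The Euler integrator below re-derives the rate expressions from first
principles with plain scalar arithmetic; it shares no code with the
package's right-hand side or integrator.
"""

from __future__ import annotations

from denitkin import KineticParams, SystemState

DEFAULT_KS = 0.01  # fallback half-saturation for organics, g-C/dm3


def euler_trajectory(
    initial: SystemState, p: KineticParams, t_grid, dt: float = 1e-4
) -> list[list[float]]:
    """Fixed-step forward-Euler trajectory recorded at the grid times.

    Returns one row per grid time: [sS_1..sS_n, sNO3, xB, cumN2, cumCO2, xI].
    Within each grid interval the step is adjusted to divide the interval
    exactly (staying within ~dt), so grid times are hit without offset.
    """
    labels = [pool.label for pool in initial.pools]
    n = len(labels)
    k3 = [p.k3_per_pool[lab] for lab in labels]
    KsS = [p.KsS_per_pool.get(lab, DEFAULT_KS) for lab in labels]
    i_bd = labels.index("biomass_derived") if "biomass_derived" in labels else -1

    sS = [pool.sS for pool in initial.pools]
    sNO3, xB = initial.sNO3, initial.xB
    cumN2, cumCO2, xI = initial.cumN2, initial.cumCO2, initial.xI

    rows = [list(sS) + [sNO3, xB, cumN2, cumCO2, xI]]
    times = list(t_grid)
    for t0, t1 in zip(times[:-1], times[1:]):
        n_steps = max(1, round((t1 - t0) / dt))
        h = (t1 - t0) / n_steps
        for _ in range(n_steps):
            mn = sNO3 / (p.KsNO3 + sNO3) if sNO3 > 0 else 0.0
            growth = [
                k3[i] * (sS[i] / (KsS[i] + sS[i]) if sS[i] > 0 else 0.0) * mn * xB
                for i in range(n)
            ]
            cons = [g / p.x_yield for g in growth]
            total_cons = sum(cons)
            death = p.bH * xB
            for i in range(n):
                sS[i] = max(sS[i] - h * cons[i], 0.0)
            if i_bd >= 0:
                sS[i_bd] += h * p.f_recycle * death
            sNO3 = max(sNO3 - h * p.z_nc * total_cons, 0.0)
            xB = max(xB + h * (sum(growth) - death), 0.0)
            cumN2 += h * p.z_nc * total_cons
            cumCO2 += h * (1.0 - p.x_yield) * total_cons
            xI += h * (1.0 - p.f_recycle) * death
        rows.append(list(sS) + [sNO3, xB, cumN2, cumCO2, xI])
    return rows
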