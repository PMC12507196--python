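"""Walk through the daily stress and performance equations for one agent.

Evaluates each component by hand for a mid-mission day and shows how they
combine into overall stress and performance — useful for sanity-checking a
configuration before committing to a long Monte Carlo.
"""

from marscrew import reference_parameters
from marscrew.stress import (
    StressComponents,
    effective_fatigue,
    overall_stress,
    performance,
    personality_factor,
    sleep_hours,
    social_stress,
    time_pressure,
)

p = reference_parameters()

pf = personality_factor(neuroticism=0.3, conscientiousness=0.8)
es = 1.2          # 20% more tasks than the crew average
tp = time_pressure(t_required=5.5, t_available=p.t_available)
ss = social_stress(cl=0.25, ssu=0.75, agreeableness=0.7, cl_max=p.cl_max, ssu_max=p.ssu_max)
sh = sleep_hours(0.7)  # yesterday's stress cuts tonight's sleep
ef = effective_fatigue(sh, cw=100.0, cw_max=p.cw_max)
envs = p.envs_base

s = overall_stress(StressComponents(pf=pf, es=es, tp=tp, ss=ss, envs=envs, ef=ef), p.weights)
perf = performance(s, p.k, p.s_opt)

print(f"personality factor PF = N - 0.5C          = {pf:+.3f}")
print(f"task-demand stress ES                     = {es:.3f}")
print(f"time pressure TP = T_req/T_avail          = {tp:.3f}")
print(f"social stress SS (support-dominated)      = {ss:+.3f}")
print(f"sleep on yesterday's stress 0.70          = {sh:.2f} h")
print(f"effective fatigue EF (sleep debt + load)  = {ef:.3f}")
print(f"environmental stress EnvS (baseline)      = {envs:.2f}")
print(f"overall stress S (weighted sum, clamped)  = {float(s):.3f}")
print(f"performance P = exp(-k (S - S_opt)^2)     = {float(perf):.3f}")
print("\nperformance peaks at exactly 1.0 when S equals the optimum "
      f"{p.s_opt}: P({p.s_opt}) = {float(performance(p.s_opt, p.k, p.s_opt)):.1f}")
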