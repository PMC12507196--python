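"""Track social-tie formation inside one crew.

Runs a 200-day mission for a personality-heterogeneous crew and prints how
each astronaut's average pairwise cohesion (mean tie strength with the five
others) evolves, plus the team-level support-minus-conflict cohesion index.
Agreeable, emotionally stable pairs accumulate positive interactions and
their mutual ties strengthen; tense pairs erode theirs.
"""

import numpy as np

from marscrew import TeamConfiguration, reference_parameters, run_mission
from marscrew.social import agent_cohesion

params = reference_parameters().replace(mission_days=200)
traj = run_mission(TeamConfiguration("C"), params, seed=11)

days = sorted(traj.cohesion_snapshots)
print("agent-level average pairwise cohesion (snapshot every 50 days):")
print("day  " + "".join(f"   A{i+1}" for i in range(traj.n_agents)))
for day in days[::5] + [days[-1]]:
    m = traj.cohesion_snapshots[day]
    row = "".join(f"{agent_cohesion(m, i):6.2f}" for i in range(traj.n_agents))
    print(f"{day:>4} {row}")

tc = traj.team_cohesion
print(f"\nteam cohesion (support - conflict balance): "
      f"start {tc[0]:.2f}, mean {np.mean(tc):.2f}, final {tc[-1]:.2f}")
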