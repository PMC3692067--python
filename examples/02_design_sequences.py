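"""Run a scaled-down design job end to end.

Pre-processing, Z-score-guided Metropolis Monte Carlo search (2
trajectories x 500 sweeps here; the standard operating point is 10 x
30,000), decoy clustering and design selection. Prints the ranked designs
with their confidence score (lower = better), identity to the scaffold,
and normalized relative errors (negative = the design sequence fits the
scaffold structure better than the native sequence, as judged by the
feature predictor).
"""
from profdesign import DesignConfig, FamilySpec, make_family, run_job

scaffold, members, _ = make_family(FamilySpec(n_members=15, length=40, seed=0))
config = DesignConfig(n_traj=2, n_sweeps=500, burn_in=100,
                      n_baseline=500, seed=1)
result = run_job(scaffold, members, config)

print(f"pooled decoys: {len(result.pool)} "
      f"(= n_traj x (n_sweeps - burn_in) = 2 x 400)")
print(f"{'rank':>4} {'score':>8} {'ident%':>7} {'size':>6}  "
      f"{'NRE_ss':>7} {'NRE_sa':>7}")
for r in result.reports:
    nre_ss = "undef" if r.nre_ss is None else f"{r.nre_ss:+.2f}"
    nre_sa = "undef" if r.nre_sa is None else f"{r.nre_sa:+.2f}"
    print(f"{r.rank:>4} {r.design_score:>8.2f} {r.identity_pct:>7.1f} "
          f"{r.cluster_size:>6} {nre_ss:>7} {nre_sa:>7}")
print("\nbest design :", result.reports[0].sequence)
print("scaffold    :", scaffold.sequence)
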