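"""Variable-N takeover model: when do CSF3R mutants replace the marrow?

Runs the hybrid stochastic/deterministic Moran model on the age-calibrated
CMP trajectory: mutants accumulate neutrally through fetal life and
infancy, then gain selective advantage s when G-CSF therapy starts at six
months.  Prints mean replacement ages over a small (mu, s) nomogram and
inverts the model for the s that yields replacement at 13 years.
"""

from scnclone import build_reference_trajectory, selection_for_age, sweep_nomogram

traj = build_reference_trajectory(t_max_years=60.0)

ages = sweep_nomogram(
    mu_grid=[1e-9, 2.5e-9, 5e-9],
    s_grid=[0.008, 0.014, 0.054],
    trajectory=traj,
    reps=15,
    seed=0,
    t_max_years=60.0,
)
print("mean age at replacement (years); rows mu, columns s:")
print(ages.round(1).to_string())

s13 = selection_for_age(2.5e-9, 13.0, traj, reps=20, seed=0)
print(f"\nselection coefficient for replacement at 13 yr (mu = 2.5e-9): "
      f"s = {s13:.4f}")
print(
    "\nReading: with a mutation rate in the normal human range (~1e-9) a "
    "selection coefficient of only ~0.01-0.05 drives full clonal "
    "replacement -- secondary MDS onset -- between ages 4 and 25."
)
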