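"""Static torque balance: what wind can a measured plant withstand?

Builds a plant from typical field measurements, balances it under a
tester pull, and converts the pull moment into the equivalent steady
wind pressure.
"""

from stalkpull import (
    PlantBody,
    PullState,
    WindLoad,
    equivalent_wind_pressure,
    pull_equilibrium,
    wind_equilibrium,
)

# a grain-filling plant: 0.9 kg stalk, 0.35 kg ear, arms from the base
plant = PlantBody(m1=0.9, m2=0.35, L2=0.55, L3=1.30)

# tester clamped at ear height (1.2 m), shaft tilted 45 deg, reading 14.7 N
pull = PullState(theta=45.0, F_theta=14.7, L=1.2)
balance = pull_equilibrium(plant, pull)
print(f"root reactions: Fox = {balance.Fox:.2f} N, Foy = {balance.Foy:.2f} N")
print(f"base resistance moment Mo = {balance.Mo:.2f} N m")

# the same overturning moment expressed as wind pressure over 0.35 m^2
# of windward area acting at 1.0 m
pressure = equivalent_wind_pressure(pull, wind_area=0.35, L1=1.0)
print(f"equivalent steady wind pressure: {pressure:.1f} Pa")

# and back: that wind load reproduces the pull moment
wind = WindLoad(P=pressure, S=0.35, L1=1.0)
print(f"wind-case Mo = {wind_equilibrium(plant, wind).Mo:.2f} N m "
      "(matches the pull case)")
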