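# Reference rig configuration.
# The plant is given in calibration form: the published net ramp slopes over
# 30-40 / 40-42 / 42-44 degC and the relay on-fraction at the 42 degC plateau;
# the loader inverts these in closed form (L0 = duty*s2/(1-duty), h_i = s_i + L0).
# Sensing is noiseless (the reference/acceptance condition).

[plant]
net_slopes = [3.375, 0.291, 0.136]
duty = 0.205
breakpoints = [30.0, 40.0, 42.0, 44.0]
anchor_index = 1
chamber_temp = 20.0
body_baseline = 37.0
body_drift = -0.03
water_mass_g = 100.0
water_power_fraction = 0.9900990099009901

[plant.magnetron]
frequency_mhz = 2450.0
power_w = 1000.0
filament_v = 4.4
filament_a = 14.0
anode_v = 4500.0

[sensor]
sample_rate_hz = 10000.0
noise_sd = 0.0
spike_prob = 0.0
spike_amp = 5.0
resolution = 0.01

[controller]
filter_window = 10
band_width = 0.1
control_interval = 10
stages = [[40.0, 20.0], [42.0, 20.0], [44.0, 20.0]]
control_channels = ["T1a", "T1b"]

[protocol]
initial_T1 = 30.0
initial_T2 = 37.0
seed = 0
sim_dt = 0.001
record_rate_hz = 100.0
max_sim_time = 300.0
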