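# Default population-level simulator parameters (version-controlled tuning
# choices, not measured facts). Chosen so that, qualitatively: second-order
# pursuit has longer latency, lower acceleration/velocity and more saccades
# than first-order; pursuit responses are later than fixation; and the
# second-order response at 3 deg/s is earlier than first-order.
version: 1
latency_mean_ms:
  pursuit_first_order: 120.0
  pursuit_second_order: 160.0
latency_sd_ms:
  pursuit_first_order: 8.0
  pursuit_second_order: 8.0
accel_mean:            # deg/s^2, initial pursuit acceleration
  pursuit_first_order: 25.0
  pursuit_second_order: 20.0
pursuit_gain:          # steady-state eye velocity / target velocity
  pursuit_first_order: {3.0: 0.95, 4.0: 0.95, 5.0: 0.95}
  pursuit_second_order: {3.0: 0.80, 4.0: 0.80, 5.0: 0.80}
saccade_rate_hz:       # catch-up saccade Poisson rate during presentation
  fixation: 0.0
  pursuit_first_order: 0.5
  pursuit_second_order: 1.5
blink_prob: 0.10
fixation_noise_sd_deg: 0.006
# Perceived-speed gain per condition x velocity; derived from the package's
# response model so that noise-free cell means land near plausible human
# reaction times (gain > 1 -> early response, < 1 -> late).
perceptual_gain:
  fixation: {3.0: 1.123, 4.0: 0.920, 5.0: 0.834}
  pursuit_first_order: {3.0: 1.053, 4.0: 0.891, 5.0: 0.757}
  pursuit_second_order: {3.0: 1.139, 4.0: 0.880, 5.0: 0.746}
timing_cv: 0.09        # multiplicative (scalar) timing noise, CV
motor_sd_ms: 30.0      # additive motor noise on the button press
decay_tau_ms: 200.0    # post-occlusion eye-velocity decay constant
noise_cutoff_hz: 8.0   # shaping cutoff of the positional noise
min_saccade_amp_deg: 0.8
between_subject:       # SDs of per-observer jitter around the population
  latency_mean_ms: 8.0
  accel_mean: 2.0
  pursuit_gain: 0.03
  perceptual_gain: 0.04
  timing_cv: 0.015
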