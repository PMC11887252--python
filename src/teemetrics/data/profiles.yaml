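# Default skill profiles for the synthetic trainee generator.
#
# Attempts follow a mean-reverting (Ornstein-Uhlenbeck) search toward each
# view's target control state, Euler-Maruyama discretized at dt = 0.1 s:
#   gain          attraction rate toward the target, 1/s
#   noise         multiplier on the per-coordinate diffusion scales below
#   settle_hold   fraction of the noise retained once the pass threshold is
#                 first reached (ability to hold the view)
#   timeout       maximum attempt duration, s
#   perforation_prob  per-attempt probability of a perforation event
#   seek_detour   amplitude multiplier of the random initial offset from the
#                 previous view's state (novice "wandering" phase)
#
# coordinate_noise_scales are diffusion scales at noise = 1 (units/sqrt(s));
# detour_scales set the initial-offset amplitude at seek_detour = 1.
# gain_sigma / noise_sigma are log-normal spreads of per-student draws.
coordinate_noise_scales:
  depth: 0.4
  rotation: 4.0
  ante_retro: 2.5
  left_right: 2.0
  omniplane: 3.0
detour_scales:
  depth: 4.0
  rotation: 35.0
  ante_retro: 8.0
  left_right: 8.0
  omniplane: 25.0
profiles:
  novice:
    gain: 0.028
    noise: 1.6
    settle_hold: 0.65
    timeout: 240.0
    perforation_prob: 0.02
    seek_detour: 2.0
  trained:
    gain: 0.075
    noise: 0.85
    settle_hold: 0.45
    timeout: 240.0
    perforation_prob: 0.005
    seek_detour: 0.9
  expert:
    gain: 1.5
    noise: 0.02
    settle_hold: 0.2
    timeout: 60.0
    perforation_prob: 0.0
    seek_detour: 0.0
cohort:
  n_students: 26
  improvement_fraction: 0.85
  gain_sigma: 0.30
  noise_sigma: 0.20
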