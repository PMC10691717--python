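# Parameter file schema

One flat YAML map per (group size, light condition), keys = `LightParams`
fields.  Packaged defaults exist for group sizes 1, 2, 5, 25 and light
levels 0.5, 1, 1.5, 5, 50 lx (`n<N>_lx<label>.yaml`, `.` written `p`).

| key        | unit  | meaning                                                          |
|------------|-------|------------------------------------------------------------------|
| label      | lx    | light level of the condition                                     |
| gamma_R    | rad   | sd of the spontaneous per-kick heading change far from the wall  |
| alpha      | —     | near-wall reduction of the spontaneous noise, in (0, 1)          |
| gamma_w    | rad   | intensity of the wall repulsion                                  |
| l_w        | mm    | range of the wall repulsion (and of the noise reduction)         |
| l_w_noise  | mm    | optional override of the noise-reduction range (defaults to l_w) |
| tau0       | s     | decay time of the glide speed within a kick                      |
| tau_bar    | s     | mean of the (untruncated) kick-duration sampler                  |
| tau_min    | s     | kick durations below this are resampled                          |
| v_bar      | mm/s  | mean of the peak-speed sampler (single-fish kick lengths)        |
| v_min      | mm/s  | optional lower truncation of the peak-speed sampler              |
| gamma_att  | —     | intensity of the attraction interaction                          |
| l_att      | mm    | range of the attraction interaction                              |
| d_att      | mm    | distance below which attraction turns repulsive                  |
| gamma_ali  | —     | intensity of the alignment interaction                           |
| l_ali      | mm    | range of the alignment interaction                               |
| d_ali      | mm    | fixed scale making gamma_ali dimensionless                       |
| gamma_m    | —     | intensity of the kick-length modulation with neighbor distance   |
| l_m        | mm    | saturation kick length at large distance                         |
| d_m        | mm    | offset of the modulation (max effect at l_m − d_m)               |
| l_c        | mm    | comfort distance kept to the wall in the kick-acceptance rule    |
| l_bar      | mm    | mean kick length used for groups of 3 or more                    |
| k          | —     | number of most influential neighbors a fish attends to           |

Provenance: `gamma_R` (group sizes 1 and 2), `tau0`, and the 50 lx
`tau_bar`/`tau_min` are the measured per-condition values; `tau_bar` at the
other light levels and `v_bar`/`l_bar` are derived from the measured mean
kick durations and lengths per condition.  All interaction strengths and
ranges (`gamma_w`, `l_w`, `alpha`, `l_c`, attraction, alignment,
modulation) and the group-table `gamma_R` are synthetic placeholders: the
original per-condition tables are not redistributable, so these values
were chosen once to place the simulator in the qualitative regimes
reported for each group size (wall-following singletons, cohesive pairs,
polarized 5-fish schools, tank-spanning rotating 25-fish groups), with
trends across light matching the reported ones (interaction strength and
range grow with illumination; alignment intensity decreases while its
range grows).
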