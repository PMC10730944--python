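# band_limit_fraction: 0.6666666666666666
# box_xy_A: 80.0
# density_g_cm3: 0.94
# molecule_mode: rigid
# n_boxes: 4
# seed: 20240201
# slice_thickness_A: 5.0
pixel_area	mean_ratio	variance_ratio
0.01	1	1.033365
0.04	1	0.92711504
0.09	0.99998585	0.79350201
0.16	0.99998585	0.66720377
0.25	0.99998585	0.55515585
0.36	0.99998585	0.4666774
0.49	0.99998585	0.3922216
0.64	0.99998585	0.30931269
0.81	0.99998585	0.23004924
1	0.99945159	0.16147122
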