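measure	genotype	rigidity_kpa	mean	sem
nuclear_height_um	KDEL	1	4.3	0.2
nuclear_height_um	KDEL	308	3.0	0.1
nuclear_height_um	SUN1L	1	3.9	0.1
nuclear_height_um	SUN1L	308	3.0	0.1
nuclear_xz_aspect	KDEL	1	0.25	0.01
nuclear_xz_aspect	KDEL	308	0.17	0.01
nuclear_xz_aspect	SUN1L	1	0.25	0.01
nuclear_xz_aspect	SUN1L	308	0.14	0.01
nuclear_xy_aspect	KDEL	1	0.75	0.01
nuclear_xy_aspect	KDEL	308	0.72	0.01
nuclear_xy_aspect	SUN1L	1	0.81	0.01
nuclear_xy_aspect	SUN1L	308	0.70	0.01
cell_spreading_area_um2	KDEL	1	1250	80
cell_spreading_area_um2	KDEL	308	2600	200
cell_spreading_area_um2	SUN1L	1	830	40
cell_spreading_area_um2	SUN1L	308	2300	100
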