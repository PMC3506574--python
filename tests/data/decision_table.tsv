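variant_class	region	flag	nmd	label	hold_reason
NONSENSE_SNP	UPSTREAM_ALL	0	0	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	UPSTREAM_ALL	0	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	UPSTREAM_ALL	1	0	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	UPSTREAM_ALL	1	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	WITHIN_DOMAIN	0	0	HOLD	OTHER
NONSENSE_SNP	WITHIN_DOMAIN	0	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	WITHIN_DOMAIN	1	0	DESTABILIZING_DOMINANT	-
NONSENSE_SNP	WITHIN_DOMAIN	1	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	NEAR_DOMAIN_EDGE	0	0	HOLD	NEAR_EDGE
NONSENSE_SNP	NEAR_DOMAIN_EDGE	0	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	NEAR_DOMAIN_EDGE	1	0	HOLD	NEAR_EDGE
NONSENSE_SNP	NEAR_DOMAIN_EDGE	1	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	LINKER	0	0	POSSIBLY_NOT_DESTABILIZING	-
NONSENSE_SNP	LINKER	0	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	LINKER	1	0	POSSIBLY_NOT_DESTABILIZING	-
NONSENSE_SNP	LINKER	1	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	DOWNSTREAM_ALL	0	0	NOT_DESTABILIZING	-
NONSENSE_SNP	DOWNSTREAM_ALL	0	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	DOWNSTREAM_ALL	1	0	NOT_DESTABILIZING	-
NONSENSE_SNP	DOWNSTREAM_ALL	1	1	DESTABILIZING_RECESSIVE	-
NONSENSE_SNP	NO_STRUCTURE	0	0	HOLD	NO_STRUCTURE
NONSENSE_SNP	NO_STRUCTURE	0	1	HOLD	NO_STRUCTURE
NONSENSE_SNP	NO_STRUCTURE	1	0	HOLD	NO_STRUCTURE
NONSENSE_SNP	NO_STRUCTURE	1	1	HOLD	NO_STRUCTURE
FRAMESHIFT_INDEL	UPSTREAM_ALL	0	0	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	UPSTREAM_ALL	0	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	UPSTREAM_ALL	1	0	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	UPSTREAM_ALL	1	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	WITHIN_DOMAIN	0	0	HOLD	OTHER
FRAMESHIFT_INDEL	WITHIN_DOMAIN	0	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	WITHIN_DOMAIN	1	0	DESTABILIZING_DOMINANT	-
FRAMESHIFT_INDEL	WITHIN_DOMAIN	1	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	NEAR_DOMAIN_EDGE	0	0	HOLD	NEAR_EDGE
FRAMESHIFT_INDEL	NEAR_DOMAIN_EDGE	0	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	NEAR_DOMAIN_EDGE	1	0	HOLD	NEAR_EDGE
FRAMESHIFT_INDEL	NEAR_DOMAIN_EDGE	1	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	LINKER	0	0	POSSIBLY_NOT_DESTABILIZING	-
FRAMESHIFT_INDEL	LINKER	0	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	LINKER	1	0	POSSIBLY_NOT_DESTABILIZING	-
FRAMESHIFT_INDEL	LINKER	1	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	DOWNSTREAM_ALL	0	0	NOT_DESTABILIZING	-
FRAMESHIFT_INDEL	DOWNSTREAM_ALL	0	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	DOWNSTREAM_ALL	1	0	NOT_DESTABILIZING	-
FRAMESHIFT_INDEL	DOWNSTREAM_ALL	1	1	DESTABILIZING_RECESSIVE	-
FRAMESHIFT_INDEL	NO_STRUCTURE	0	0	HOLD	NO_STRUCTURE
FRAMESHIFT_INDEL	NO_STRUCTURE	0	1	HOLD	NO_STRUCTURE
FRAMESHIFT_INDEL	NO_STRUCTURE	1	0	HOLD	NO_STRUCTURE
FRAMESHIFT_INDEL	NO_STRUCTURE	1	1	HOLD	NO_STRUCTURE
INFRAME_INDEL	UPSTREAM_ALL	0	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	UPSTREAM_ALL	0	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	UPSTREAM_ALL	1	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	UPSTREAM_ALL	1	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	WITHIN_DOMAIN	0	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	WITHIN_DOMAIN	0	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	WITHIN_DOMAIN	1	0	DESTABILIZING_RECESSIVE	-
INFRAME_INDEL	WITHIN_DOMAIN	1	1	DESTABILIZING_RECESSIVE	-
INFRAME_INDEL	NEAR_DOMAIN_EDGE	0	0	HOLD	NEAR_EDGE
INFRAME_INDEL	NEAR_DOMAIN_EDGE	0	1	HOLD	NEAR_EDGE
INFRAME_INDEL	NEAR_DOMAIN_EDGE	1	0	HOLD	NEAR_EDGE
INFRAME_INDEL	NEAR_DOMAIN_EDGE	1	1	HOLD	NEAR_EDGE
INFRAME_INDEL	LINKER	0	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	LINKER	0	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	LINKER	1	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	LINKER	1	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	DOWNSTREAM_ALL	0	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	DOWNSTREAM_ALL	0	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	DOWNSTREAM_ALL	1	0	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	DOWNSTREAM_ALL	1	1	POSSIBLY_NOT_DESTABILIZING	-
INFRAME_INDEL	NO_STRUCTURE	0	0	HOLD	NO_STRUCTURE
INFRAME_INDEL	NO_STRUCTURE	0	1	HOLD	NO_STRUCTURE
INFRAME_INDEL	NO_STRUCTURE	1	0	HOLD	NO_STRUCTURE
INFRAME_INDEL	NO_STRUCTURE	1	1	HOLD	NO_STRUCTURE
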