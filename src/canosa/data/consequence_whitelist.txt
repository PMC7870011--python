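coding_unknown
essential_splice_site
essential_splice_site, coding_unknown, intronic
essential_splice_site, intronic
essential_splice_site, within_non_coding_gene
frameshift_coding
frameshift_coding, non_synonymous_coding
frameshift_coding, splice_site
frameshift_coding, splice_site, intronic
non_synonymous_coding
non_synonymous_coding, splice_site
splice_site, intronic
splice_site, intronic, within_non_coding_gene
splice_site, synonymous_coding
splice_site, within_non_coding_gene, within_non_coding_gene
stop_gained
stop_gained, frameshift_coding
stop_gained, splice_site
stop_lost
within_mature_mirna
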