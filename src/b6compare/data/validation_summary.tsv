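# Validation bookkeeping for the SNP/small-indel genotyping campaign (Sequenom/pyrosequencing/Sanger; panel of four B6J and four B6N samples)
field	count
assayed_snps	762
assayed_indels	169
eliminated	363
confirmed_coding_snps	34
confirmed_coding_indels	2
confirmed_noncoding_snps	146
confirmed_noncoding_indels	54
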