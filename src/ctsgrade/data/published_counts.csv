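# Published per-category hand counts for the three CTS severity scales as
# printed in the source study's summary tables: the revised-scale cohort
# (2246 hands, North Wales, one calendar year), the Padua reference cohort
# (600 hands) and the Bland reference cohort.
# Note: the Bland category counts below sum to 8141 while the printed total
# is 8501; the discrepancy is preserved as printed (see cohort_stats
# PUBLISHED_TOTALS, which keeps 8501 as the percentage denominator).
scheme,order,category,count
revised,0,Normal,968
revised,1,Early,271
revised,2,Mild Sensory,215
revised,3,Mild Sensory-Motor,51
revised,4,Moderate Sensory,134
revised,5,Moderate Sensory-Motor,356
revised,6,Severe Sensory-Motor,204
revised,7,Extremely Severe Sensory-Motor,33
revised,8,Complete,14
padua,0,Normal,18
padua,1,Minimal,123
padua,2,Mild,145
padua,3,Moderate,217
padua,4,Severe,81
padua,5,Extremely severe,16
bland,0,Normal,3269
bland,1,Very mild,684
bland,2,Mild sensory-motor,944
bland,3,Moderately severe,1359
bland,4,Severe,568
bland,5,Very severe,930
bland,6,Extremely severe,387
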