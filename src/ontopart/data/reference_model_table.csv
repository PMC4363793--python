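scheme,n_partitions,model_id,brlens,rate_multiplier,rates,n_parameters
1,11,1.2,unlinked,absent,equal,11
1,11,1.4,unlinked,absent,shared_gamma,12
1,11,1.5,linked,absent,per_partition_gamma,12
1,11,1.6,unlinked,absent,per_partition_gamma,22
1,11,1.7,linked,unlinked,equal,12
1,11,1.8,unlinked,unlinked,equal,22
1,11,1.9,linked,unlinked,shared_gamma,13
1,11,1.10,unlinked,unlinked,shared_gamma,23
1,11,1.11,linked,unlinked,per_partition_gamma,23
1,11,1.12,unlinked,unlinked,per_partition_gamma,33
2,8,2.2,unlinked,absent,equal,8
2,8,2.4,unlinked,absent,shared_gamma,9
2,8,2.5,linked,absent,per_partition_gamma,9
2,8,2.6,unlinked,absent,per_partition_gamma,16
2,8,2.7,linked,unlinked,equal,9
2,8,2.8,unlinked,unlinked,equal,16
2,8,2.9,linked,unlinked,shared_gamma,10
2,8,2.10,unlinked,unlinked,shared_gamma,17
2,8,2.11,linked,unlinked,per_partition_gamma,17
2,8,2.12,unlinked,unlinked,per_partition_gamma,24
3,6,3.2,unlinked,absent,equal,6
3,6,3.4,unlinked,absent,shared_gamma,7
3,6,3.5,linked,absent,per_partition_gamma,7
3,6,3.6,unlinked,absent,per_partition_gamma,12
3,6,3.7,linked,unlinked,equal,7
3,6,3.8,unlinked,unlinked,equal,12
3,6,3.9,linked,unlinked,shared_gamma,8
3,6,3.10,unlinked,unlinked,shared_gamma,13
3,6,3.11,linked,unlinked,per_partition_gamma,13
3,6,3.12,unlinked,unlinked,per_partition_gamma,18
4,6,4.2,unlinked,absent,equal,6
4,6,4.4,unlinked,absent,shared_gamma,7
4,6,4.5,linked,absent,per_partition_gamma,7
4,6,4.6,unlinked,absent,per_partition_gamma,12
4,6,4.7,linked,unlinked,equal,7
4,6,4.8,unlinked,unlinked,equal,12
4,6,4.9,linked,unlinked,shared_gamma,8
4,6,4.10,unlinked,unlinked,shared_gamma,13
4,6,4.11,linked,unlinked,per_partition_gamma,13
4,6,4.12,unlinked,unlinked,per_partition_gamma,18
5,7,5.2,unlinked,absent,equal,7
5,7,5.4,unlinked,absent,shared_gamma,8
5,7,5.5,linked,absent,per_partition_gamma,8
5,7,5.6,unlinked,absent,per_partition_gamma,14
5,7,5.7,linked,unlinked,equal,8
5,7,5.8,unlinked,unlinked,equal,14
5,7,5.9,linked,unlinked,shared_gamma,9
5,7,5.10,unlinked,unlinked,shared_gamma,15
5,7,5.11,linked,unlinked,per_partition_gamma,15
5,7,5.12,unlinked,unlinked,per_partition_gamma,21
6,6,6.2,unlinked,absent,equal,6
6,6,6.4,unlinked,absent,shared_gamma,7
6,6,6.5,linked,absent,per_partition_gamma,7
6,6,6.6,unlinked,absent,per_partition_gamma,12
6,6,6.7,linked,unlinked,equal,7
6,6,6.8,unlinked,unlinked,equal,12
6,6,6.9,linked,unlinked,shared_gamma,8
6,6,6.10,unlinked,unlinked,shared_gamma,13
6,6,6.11,linked,unlinked,per_partition_gamma,13
6,6,6.12,unlinked,unlinked,per_partition_gamma,18
7,4,7.2,unlinked,absent,equal,4
7,4,7.4,unlinked,absent,shared_gamma,5
7,4,7.5,linked,absent,per_partition_gamma,5
7,4,7.6,unlinked,absent,per_partition_gamma,8
7,4,7.7,linked,unlinked,equal,5
7,4,7.8,unlinked,unlinked,equal,8
7,4,7.9,linked,unlinked,shared_gamma,6
7,4,7.10,unlinked,unlinked,shared_gamma,9
7,4,7.11,linked,unlinked,per_partition_gamma,9
7,4,7.12,unlinked,unlinked,per_partition_gamma,12
8,5,8.2,unlinked,absent,equal,5
8,5,8.4,unlinked,absent,shared_gamma,6
8,5,8.5,linked,absent,per_partition_gamma,6
8,5,8.6,unlinked,absent,per_partition_gamma,10
8,5,8.7,linked,unlinked,equal,6
8,5,8.8,unlinked,unlinked,equal,10
8,5,8.9,linked,unlinked,shared_gamma,7
8,5,8.10,unlinked,unlinked,shared_gamma,11
8,5,8.11,linked,unlinked,per_partition_gamma,11
8,5,8.12,unlinked,unlinked,per_partition_gamma,15
9,1,9.1,linked,absent,equal,1
9,1,9.3,linked,absent,shared_gamma,2
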